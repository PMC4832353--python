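"""Core domain types and I/O for the footprinting pipeline.

Coordinates are 0-based half-open everywhere inside the package; the only
1-based inclusive representation is the ``TSV1`` table dialect used for
printed hit tables, converted at the I/O boundary.  Minus-strand features
are stored coordinate-sorted (start < end) with a strand flag, never with
swapped start/end.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("cnsfoot")

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Column order of the printed hit-table dialect (1-based inclusive coords).
TSV1_COLUMNS = (
    "ref_start", "ref_end", "clone", "query_start", "query_end",
    "pct_identity", "length", "mismatches", "gap_opens", "evalue",
    "bitscore", "footnote",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (e.g. one BAC clone or one locus)."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues outside ACGTN: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence.

    ``strand`` is '+', '-' or '.' ('.' only for unstranded features).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval on the same sequence."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AnnotationTrack:
    """A named set of labeled intervals of one category.

    category is one of {coding, repeat, enhancer, UTR, other}.
    """

    name: str
    category: str = "other"
    intervals: list[GenomicInterval] = field(default_factory=list)

    CATEGORIES = ("coding", "repeat", "enhancer", "UTR", "other")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown track category {self.category!r}")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def for_seq(self, seq_id: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.seq_id == seq_id]


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Lowercase residues are uppercased; characters outside ACGTN are replaced
    by N with one logged warning per record.  Duplicate ids or an empty file
    raise ValueError.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        n_bad = sum(1 for c in residues if c not in DNA_ALPHABET)
        if n_bad:
            logger.warning(
                "record %s: %d non-ACGTN residue(s) replaced by N",
                rec.id, n_bad)
            residues = "".join(
                c if c in DNA_ALPHABET else "N" for c in residues)
        records.append(SequenceRecord(id=rec.id, residues=residues,
                                      species=species))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval track I/O: BED, GFF3 and the printed-table (TSV1) dialect
# ---------------------------------------------------------------------------

DIALECTS = ("BED", "GFF3", "TSV1")


def _parse_int(tok: str) -> int:
    # printed tables use thin spaces as thousands separators
    return int(tok.replace(" ", "").replace(" ", ""))


def read_intervals(path: str | Path, dialect: str, name: str = "",
                   category: str = "other",
                   seq_lengths: dict[str, int] | None = None,
                   ) -> AnnotationTrack:
    """Read an annotation track; all coordinates normalised to 0-based
    half-open.

    TSV1 rows are 1-based inclusive; a row whose query coordinates are
    printed descending (start > end) denotes a minus-strand match and is
    stored coordinate-sorted with strand '-'.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    track = AnnotationTrack(name=name or Path(path).stem, category=category)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                iv = _parse_interval_row(fields, dialect)
            except Exception as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {dialect} row: {exc}"
                ) from exc
            if seq_lengths is not None:
                limit = seq_lengths.get(iv.seq_id)
                if limit is not None and iv.end > limit:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {iv.end} exceeds "
                        f"length {limit} of sequence {iv.seq_id!r}")
            track.intervals.append(iv)
    return track


def _parse_interval_row(fields: Sequence[str], dialect: str) -> GenomicInterval:
    if dialect == "BED":
        seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 else "."
        return GenomicInterval(seq_id, start, end, strand, label)
    if dialect == "GFF3":
        seq_id = fields[0]
        start, end = int(fields[3]) - 1, int(fields[4])
        strand = fields[6] if fields[6] in "+-" else "."
        label = ""
        if len(fields) > 8:
            for kv in fields[8].split(";"):
                if kv.startswith(("ID=", "Name=")):
                    label = kv.split("=", 1)[1]
                    break
        return GenomicInterval(seq_id, start, end, strand, label)
    # TSV1: query-side interval of a printed hit row
    seq_id = fields[2]
    a, b = _parse_int(fields[3]), _parse_int(fields[4])
    if a <= b:
        return GenomicInterval(seq_id, a - 1, b, "+", fields[0])
    return GenomicInterval(seq_id, b - 1, a, "-", fields[0])


def write_intervals(track: AnnotationTrack, path: str | Path,
                    dialect: str) -> None:
    """Write a track; read_intervals(write_intervals(x)) round-trips."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "BED":
            fh.write(f"track name={track.name}\n")
            for iv in track.intervals:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t"
                         f"{iv.label}\t0\t{iv.strand}\n")
        elif dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for iv in track.intervals:
                fh.write(f"{iv.seq_id}\t{track.name}\t{track.category}\t"
                         f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                         f"Name={iv.label}\n")
        else:  # TSV1 (query side only; label column holds ref_start)
            fh.write("# TSV1 query intervals\n")
            for iv in track.intervals:
                if iv.strand == "-":
                    a, b = iv.end, iv.start + 1
                else:
                    a, b = iv.start + 1, iv.end
                fh.write(f"{iv.label}\t\t{iv.seq_id}\t{a}\t{b}\n")


def to_one_based(iv: GenomicInterval) -> tuple[int, int]:
    """1-based inclusive (start, end) pair; descending when minus strand."""
    if iv.strand == "-":
        return iv.end, iv.start + 1
    return iv.start + 1, iv.end


def from_one_based(seq_id: str, a: int, b: int,
                   label: str = "") -> GenomicInterval:
    """Inverse of :func:`to_one_based`."""
    if a <= b:
        return GenomicInterval(seq_id, a - 1, b, "+", label)
    return GenomicInterval(seq_id, b - 1, a, "-", label)
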