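"""Loaders for the packaged reference-locus fixtures.

The fixtures transcribe the published clone summary and conserved-block
hit table for the blowfly achaete-scute locus.  Reference ("dmel")
coordinates are local to the 120-kb reference window; query coordinates
are local to the sequenced BAC clones.  Where only
aggregates are published (per-clone repeat counts/bp, the
second-reference comparison, enhancer positions), the loaders
reconstruct deterministic synthetic
stand-ins that are exact for every aggregate quantity the pipeline
computes; those objects are labelled synthetic.
"""
from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .annotate_report import DEFAULT_CATEGORY_MAP
from .cns_detect import LocalHit
from .contig_map import Anchor, CloneMap, build_clone_map
from .seqmodel import AnnotationTrack, GenomicInterval, read_intervals

REF_ID = "dmel"
REF_LOCUS = GenomicInterval(REF_ID, 0, 120_000)

#: Clone order along the contig (left to right across the locus).
CLONE_ORDER = ("113H10", "99M22", "97L04", "62B24", "16B10", "104L14")

IDENTICAL_OVERLAP_BP = 38_828
ALLELIC_OVERLAP_BP = 83_000

#: Anchor spread between overlapping clones reflects allelic indels, so
#: the packaged map is built with an indel-scale tolerance.
ALLELIC_TOLERANCE_BP = 2_000


def _data(name: str) -> Path:
    return Path(str(resources.files("cnsfoot").joinpath("data", name)))


def _read_tsv(name: str) -> list[dict[str, str]]:
    with open(_data(name)) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def table2_hits() -> list[LocalHit]:
    """The 28 cross-validated conserved noncoding blocks.

    Reference coordinates are converted from the printed 1-based inclusive
    values to 0-based half-open; query rows printed with descending
    coordinates become minus-strand hits.  Raw scores are not printed and
    are stored as 0.
    """
    hits = []
    for row in _read_tsv("table2_blocks.tsv"):
        rs, re_ = int(row["ref_start"]), int(row["ref_end"])
        qa, qb = int(row["query_start"]), int(row["query_end"])
        if qa <= qb:
            q_iv = GenomicInterval(row["clone"], qa - 1, qb, "+")
        else:
            q_iv = GenomicInterval(row["clone"], qb - 1, qa, "-")
        hits.append(LocalHit(
            ref_interval=GenomicInterval(REF_ID, rs - 1, re_, "+"),
            query_interval=q_iv, strand=q_iv.strand, raw_score=0,
            bit_score=float(row["bitscore"]), evalue=float(row["evalue"]),
            pct_identity=float(row["pct_identity"]),
            aln_length=int(row["length"]),
            mismatches=int(row["mismatches"]),
            gap_opens=int(row["gap_opens"]),
            footnote="" if row["footnote"] == "." else row["footnote"]))
    return hits


def table2_anchors() -> list[Anchor]:
    """Blocks present in two overlapping clones, as offset anchors."""
    return [Anchor(r["clone_a"], int(r["pos_a"]),
                   r["clone_b"], int(r["pos_b"]))
            for r in _read_tsv("table2_anchors.tsv")]


def clone_table() -> list[dict]:
    rows = _read_tsv("table1_clones.tsv")
    order = {c: i for i, c in enumerate(CLONE_ORDER)}
    return sorted(
        ({"clone": r["clone"], "total_bp": int(r["total_bp"]),
          "gene_count": int(r["gene_count"]), "gene_bp": int(r["gene_bp"]),
          "gene_labels": [] if r["gene_labels"] == "."
          else r["gene_labels"].split(","),
          "repeat_count": int(r["repeat_count"]),
          "repeat_bp": int(r["repeat_bp"])} for r in rows),
        key=lambda r: order[r["clone"]])


def clone_map(tolerance: float = ALLELIC_TOLERANCE_BP) -> CloneMap:
    """Contig map of the six sequenced clones from the shared-block
    anchors (abutment assumed where no anchor joins a pair)."""
    clones = [(r["clone"], r["total_bp"]) for r in clone_table()]
    return build_clone_map(clones, table2_anchors(),
                           identical_overlap_bp=IDENTICAL_OVERLAP_BP,
                           allelic_overlap_bp=ALLELIC_OVERLAP_BP,
                           tolerance=tolerance)


def table1_tracks() -> tuple[list[tuple[str, int]], AnnotationTrack,
                             AnnotationTrack]:
    """(clones, gene track, repeat track) for the clone summary.

    Only per-clone interval counts and total bp are printed, so interval
    coordinates are synthetic: genes sit at position 1000 and repeats are
    laid out as evenly sized spaced intervals summing to the printed bp,
    which is exact for every count/bp/percentage the summary reports.
    """
    clones = []
    genes = AnnotationTrack("table1_genes_synthetic", "coding")
    repeats = AnnotationTrack("table1_repeats_synthetic", "repeat")
    for row in clone_table():
        cid = row["clone"]
        clones.append((cid, row["total_bp"]))
        pos = 1000
        for label in row["gene_labels"]:
            length = row["gene_bp"] // max(1, len(row["gene_labels"]))
            genes.intervals.append(
                GenomicInterval(cid, pos, pos + length, "+", label))
            pos += length + 500
        n, bp = row["repeat_count"], row["repeat_bp"]
        if n:
            base, extra = divmod(bp, n)
            pos += 1000
            for k in range(n):
                length = base + (1 if k < extra else 0)
                repeats.intervals.append(GenomicInterval(
                    cid, pos, pos + length, "+", f"{cid}_rep{k}"))
                pos += length + 10
            if pos > row["total_bp"]:
                raise AssertionError("synthetic repeat layout overflows "
                                     f"clone {cid}")
    return clones, genes, repeats


def virilis_hits() -> list[LocalHit]:
    """Synthetic second-reference comparison for cross-validation.

    All 28 blocks are recorded as recovered against the second
    reference, but no coordinates are published for that comparison, so this
    fixture reuses the query-side intervals (recovery is defined on the
    shared query axis) with placeholder reference intervals on "dvir".
    """
    out = []
    for hit in table2_hits():
        r = hit.ref_interval
        out.append(LocalHit(
            ref_interval=GenomicInterval("dvir", r.start, r.end, "+"),
            query_interval=hit.query_interval, strand=hit.strand,
            raw_score=0, bit_score=hit.bit_score, evalue=hit.evalue,
            pct_identity=hit.pct_identity, aln_length=hit.aln_length,
            mismatches=hit.mismatches, gap_opens=hit.gap_opens))
    return out


def enhancer_track() -> AnnotationTrack:
    """Reference enhancer intervals reconstructed from the footnoted
    block-to-enhancer assignments (synthetic coordinates, exact labels)."""
    return read_intervals(_data("enhancers_dmel_synthetic.bed"), "BED",
                          name="dmel_enhancers_synthetic",
                          category="enhancer")


def category_map() -> dict[str, str]:
    out: dict[str, str] = {}
    with open(_data("enhancer_categories.cfg")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, cat = line.split("\t")
            out[label] = cat
    assert out == DEFAULT_CATEGORY_MAP
    return out
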