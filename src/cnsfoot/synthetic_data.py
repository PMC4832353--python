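"""Synthetic locus evolution with a planted truth set.

Emulates the evolutionary scenario the detection pipeline assumes: an
ancestral locus carrying intronless, co-oriented genes and short enhancer
"islands" evolves along the rooted tree ``((ref1,ref2),query)``.  Islands
and coding sequence evolve at a reduced substitution rate (purifying
selection); the noncoding background accumulates substitutions and indels
fast enough to be unalignable at the divergences studied.  On the query
branch, transposable-element (TE) copies drawn from a small internal
library are inserted (expanding the query genome, ~25% repeat content at
the default rate) and islands may flip orientation (microinversions).

Substitutions follow the Jukes–Cantor model per branch: a site differs
after a branch of ``r·t`` expected substitutions/site with probability
``(3/4)(1 - exp(-(4/3) r t))``.  Indels have geometric lengths and occur
only in unconstrained background (islands and genes are preserved intact
in every taxon, so the planted truth is a bijection across taxa).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .seqmodel import AnnotationTrack, GenomicInterval, SequenceRecord, \
    write_fasta, write_intervals

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TREE_RE = re.compile(
    r"^\(\(ref1:([\d.eE+-]+),ref2:([\d.eE+-]+)\):([\d.eE+-]+),"
    r"query:([\d.eE+-]+)\)$")

TAG_BACKGROUND = 0
_TAG_ISLAND = 1          # islands: 1 .. n_islands
_TAG_GENE = 10_000       # genes:   10000 .. 10000+n_genes-1
_TAG_TE = 20_000         # TE copies: 20000, 20001, ...


def _parse_tree(tree: str) -> tuple[float, float, float, float]:
    """Branch lengths (t_ref1, t_ref2, t_refanc, t_query) from the fixed
    topology ``((ref1:t1,ref2:t2):t3,query:t4)``."""
    m = _TREE_RE.match(tree.replace(" ", ""))
    if not m:
        raise ValueError(
            "tree must have the form ((ref1:t1,ref2:t2):t3,query:t4)")
    return tuple(float(x) for x in m.groups())  # type: ignore[return-value]


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the three-taxon locus simulation.

    Rates are expected events per site (or per kb for TEs); branch lengths
    are in expected substitutions/site at the background rate scale, so a
    query–reference path of 0.8 with ``background_sub_rate=1`` means 0.8
    substitutions/site of background divergence.
    """

    tree: str = "((ref1:0.1,ref2:0.1):0.3,query:0.4)"
    background_sub_rate: float = 1.0
    background_indel_rate: float = 0.02    # events/site per branch-length unit
    indel_mean_len: float = 3.0
    island_sub_rate: float = 0.15
    n_islands: int = 10
    island_length_range: tuple[int, int] = (20, 60)
    n_genes: int = 3
    gene_length_range: tuple[int, int] = (600, 1000)
    te_insertion_rate: float = 0.37        # events/kb, query branch only
    te_length_range: tuple[int, int] = (300, 1500)
    inversion_prob: float = 0.1
    locus_length: int = 12_000
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.background_sub_rate, self.background_indel_rate,
                  self.island_sub_rate, self.te_insertion_rate,
                  self.inversion_prob):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.island_sub_rate >= self.background_sub_rate:
            raise ValueError("island_sub_rate must be below "
                             "background_sub_rate")
        for lo, hi in (self.island_length_range, self.gene_length_range,
                       self.te_length_range):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must be nonempty and "
                                 "positive")
        _parse_tree(self.tree)


@dataclass
class TruthSet:
    """Planted feature intervals per taxon.

    Every island and gene appears in every taxon exactly once, labelled
    ``island_<i>`` / ``gene_<j>``; the identity map across taxa is the
    shared label.  TEs exist only where inserted (the query).
    """

    islands: dict[str, AnnotationTrack]
    genes: dict[str, AnnotationTrack]
    tes: dict[str, AnnotationTrack]

    def island_intervals(self, taxon: str) -> dict[str, GenomicInterval]:
        return {iv.label: iv for iv in self.islands[taxon]}


@dataclass
class RecoveryRow:
    island: str
    detected: bool


@dataclass
class RecoveryTable:
    """Per-island detection and per-hit truth assignment."""

    islands: list[RecoveryRow]
    hit_truth: list[bool]          # parallel to the input hit list

    @property
    def n_detected(self) -> int:
        return sum(r.detected for r in self.islands)

    @property
    def recovery_fraction(self) -> float:
        return self.n_detected / len(self.islands) if self.islands else 0.0

    @property
    def n_spurious(self) -> int:
        return sum(not t for t in self.hit_truth)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _jc_prob(subs_per_site: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * subs_per_site))


def _build_ancestor(p: EvolutionParams, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    lens = []
    tags = []
    for i in range(p.n_islands):
        lens.append(int(rng.integers(p.island_length_range[0],
                                     p.island_length_range[1] + 1)))
        tags.append(_TAG_ISLAND + i)
    for j in range(p.n_genes):
        lens.append(int(rng.integers(p.gene_length_range[0],
                                     p.gene_length_range[1] + 1)))
        tags.append(_TAG_GENE + j)
    footprint = sum(lens)
    if footprint >= p.locus_length:
        raise ValueError(
            f"feature footprint {footprint} bp exceeds locus length "
            f"{p.locus_length} bp")
    order = rng.permutation(len(lens))
    spare = p.locus_length - footprint
    # random gap partition: n_features+1 gaps
    cuts = np.sort(rng.integers(0, spare + 1, size=len(lens)))
    gaps = np.diff(np.concatenate([[0], cuts, [spare]]))
    seq = rng.choice(_BASES, size=p.locus_length).astype(np.uint8)
    tag = np.zeros(p.locus_length, dtype=np.int32)
    pos = 0
    for k, idx in enumerate(order):
        pos += int(gaps[k])
        tag[pos:pos + lens[idx]] = tags[idx]
        pos += lens[idx]
    return seq, tag


def _substitute(seq: np.ndarray, tag: np.ndarray, t: float,
                p: EvolutionParams, rng: np.random.Generator) -> np.ndarray:
    constrained = (tag >= _TAG_ISLAND) & (tag < _TAG_TE)
    p_bg = _jc_prob(p.background_sub_rate * t)
    p_isl = _jc_prob(p.island_sub_rate * t)
    prob = np.where(constrained, p_isl, p_bg)
    hit = rng.random(len(seq)) < prob
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        code = np.zeros(256, dtype=np.uint8)
        for b, c in idx.items():
            code[b] = c
        cur = code[seq[hit]]
        seq = seq.copy()
        seq[hit] = _BASES[(cur + shift) % 4]
    return seq


def _apply_indels(seq: np.ndarray, tag: np.ndarray, t: float,
                  p: EvolutionParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    n_events = int(rng.poisson(p.background_indel_rate * t * len(seq)))
    events = []
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq)))
        is_ins = bool(rng.random() < 0.5)
        length = int(rng.geometric(1.0 / p.indel_mean_len))
        events.append((pos, is_ins, length))
    # apply right-to-left so earlier positions stay valid
    for pos, is_ins, length in sorted(events, reverse=True):
        if tag[pos] != TAG_BACKGROUND:
            continue        # constrained features never gain or lose bases
        if is_ins:
            ins = rng.choice(_BASES, size=length).astype(np.uint8)
            seq = np.concatenate([seq[:pos], ins, seq[pos:]])
            tag = np.concatenate(
                [tag[:pos], np.zeros(length, dtype=np.int32), tag[pos:]])
        else:
            end = pos
            while end < len(seq) and end - pos < length \
                    and tag[end] == TAG_BACKGROUND:
                end += 1
            seq = np.concatenate([seq[:pos], seq[end:]])
            tag = np.concatenate([tag[:pos], tag[end:]])
    return seq, tag


def _insert_tes(seq: np.ndarray, tag: np.ndarray, p: EvolutionParams,
                library: list[np.ndarray], rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    n_events = int(rng.poisson(p.te_insertion_rate * len(seq) / 1000.0))
    copy_id = _TAG_TE
    for _ in range(n_events):
        background = np.nonzero(tag == TAG_BACKGROUND)[0]
        if not len(background):
            break
        pos = int(background[rng.integers(0, len(background))])
        master = library[int(rng.integers(0, len(library)))]
        length = int(rng.integers(p.te_length_range[0],
                                  p.te_length_range[1] + 1))
        length = min(length, len(master))
        start = int(rng.integers(0, len(master) - length + 1))
        copy = master[start:start + length].copy()
        # 5% per-copy divergence keeps copies self-similar but not identical
        mut = rng.random(length) < 0.05
        nm = int(mut.sum())
        if nm:
            idx = {65: 0, 67: 1, 71: 2, 84: 3}
            code = np.zeros(256, dtype=np.uint8)
            for b, c in idx.items():
                code[b] = c
            copy[mut] = _BASES[(code[copy[mut]]
                                + rng.integers(1, 4, nm)) % 4]
        seq = np.concatenate([seq[:pos], copy, seq[pos:]])
        tag = np.concatenate(
            [tag[:pos], np.full(length, copy_id, dtype=np.int32),
             tag[pos:]])
        copy_id += 1
    return seq, tag


def _invert_islands(seq: np.ndarray, tag: np.ndarray, p: EvolutionParams,
                    rng: np.random.Generator) -> tuple[np.ndarray, set[int]]:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    flipped: set[int] = set()
    seq = seq.copy()
    for i in range(p.n_islands):
        if rng.random() < p.inversion_prob:
            idx = np.nonzero(tag == _TAG_ISLAND + i)[0]
            if len(idx):
                seq[idx[0]:idx[-1] + 1] = comp[seq[idx[0]:idx[-1] + 1]][::-1]
                flipped.add(i)
    return seq, flipped


def _tag_track(tag: np.ndarray, taxon: str, lo: int, hi: int, prefix: str,
               category: str, flipped: set[int] | None = None
               ) -> AnnotationTrack:
    track = AnnotationTrack(name=f"{taxon}_{prefix}", category=category)
    sel = (tag >= lo) & (tag < hi)
    if not sel.any():
        return track
    for value in np.unique(tag[sel]):
        idx = np.nonzero(tag == value)[0]
        strand = "-" if flipped and (value - lo) in flipped else "+"
        track.intervals.append(GenomicInterval(
            taxon, int(idx[0]), int(idx[-1]) + 1, strand,
            f"{prefix}_{int(value - lo)}"))
    return track


def simulate_locus(params: EvolutionParams
                   ) -> tuple[dict[str, SequenceRecord], TruthSet]:
    """Simulate the three-taxon locus; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    t1, t2, t3, t4 = _parse_tree(params.tree)
    anc_seq, anc_tag = _build_ancestor(params, rng)
    te_library = [rng.choice(_BASES, size=params.te_length_range[1]
                             ).astype(np.uint8) for _ in range(4)]

    # reference-ancestor branch, then the two reference tips
    ra_seq = _substitute(anc_seq, anc_tag, t3, params, rng)
    ra_seq, ra_tag = _apply_indels(ra_seq, anc_tag, t3, params, rng)
    taxa: dict[str, tuple[np.ndarray, np.ndarray, set[int]]] = {}
    for taxon, t in (("ref1", t1), ("ref2", t2)):
        s = _substitute(ra_seq, ra_tag, t, params, rng)
        s, tg = _apply_indels(s, ra_tag, t, params, rng)
        taxa[taxon] = (s, tg, set())
    # query branch: substitutions, indels, TE expansion, microinversions
    qs = _substitute(anc_seq, anc_tag, t4, params, rng)
    qs, qt = _apply_indels(qs, anc_tag, t4, params, rng)
    qs, qt = _insert_tes(qs, qt, params, te_library, rng)
    qs, flipped = _invert_islands(qs, qt, params, rng)
    taxa["query"] = (qs, qt, flipped)

    records: dict[str, SequenceRecord] = {}
    islands: dict[str, AnnotationTrack] = {}
    genes: dict[str, AnnotationTrack] = {}
    tes: dict[str, AnnotationTrack] = {}
    for taxon, (s, tg, flip) in taxa.items():
        records[taxon] = SequenceRecord(
            id=taxon, residues=s.tobytes().decode(), species=taxon)
        islands[taxon] = _tag_track(tg, taxon, _TAG_ISLAND, _TAG_GENE,
                                    "island", "enhancer", flip)
        genes[taxon] = _tag_track(tg, taxon, _TAG_GENE, _TAG_TE,
                                  "gene", "coding")
        tes[taxon] = _tag_track(tg, taxon, _TAG_TE, 2 ** 31 - 1,
                                "te", "repeat")
    truth = TruthSet(islands=islands, genes=genes, tes=tes)
    for taxon in records:
        if len(truth.islands[taxon]) != params.n_islands:
            raise AssertionError("planted island lost during simulation")
    return records, truth


def write_simulation(records: dict[str, SequenceRecord], truth: TruthSet,
                     params: EvolutionParams, outdir: str | Path) -> None:
    """FASTA per taxon + truth BED per taxon + JSON parameter echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon, rec in records.items():
        write_fasta([rec], outdir / f"{taxon}.fa")
        for kind, tracks in (("islands", truth.islands),
                             ("genes", truth.genes), ("tes", truth.tes)):
            write_intervals(tracks[taxon],
                            outdir / f"{taxon}.{kind}.bed", "BED")
    with open(outdir / "params.json", "w") as fh:
        json.dump(asdict(params), fh, indent=2)


# ---------------------------------------------------------------------------
# recovery accounting
# ---------------------------------------------------------------------------

def truth_overlap(hits, truth: TruthSet, ref_taxon: str = "ref1",
                  query_taxon: str = "query") -> RecoveryTable:
    """Score hits against the planted islands.

    A hit is *true* iff it overlaps the same island in both coordinate
    systems (reference interval vs the island's reference copy, query
    interval vs the island's query copy).
    """
    ref_islands = truth.island_intervals(ref_taxon)
    qry_islands = truth.island_intervals(query_taxon)
    detected: dict[str, bool] = {name: False for name in ref_islands}
    hit_truth: list[bool] = []
    for hit in hits:
        ok = False
        for name, r_iv in ref_islands.items():
            if hit.ref_interval.overlap(r_iv) > 0 \
                    and hit.query_interval.overlap(qry_islands[name]) > 0:
                detected[name] = True
                ok = True
        hit_truth.append(ok)
    rows = [RecoveryRow(island=n, detected=d) for n, d in detected.items()]
    return RecoveryTable(islands=rows, hit_truth=hit_truth)
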