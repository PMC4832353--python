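"""Enhancer-overlap accounting, BAC summary tables and locus-size
estimates.

Conserved blocks are labeled with every known enhancer they overlap on the
reference axis and counted per enhancer category (wing disc, UTR,
embryonic nervous system).  Clone summaries give gene/repeat counts, bp
and percentages per sequenced clone, a totals row, and a nonredundant row
that collapses clone overlap and counts each distinct gene once.  Two
locus-size estimators are provided: proportional scaling by genome size,
and extrapolation of the sequenced span by the fraction of the reference
locus it covers.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from intervaltree import IntervalTree

from .cns_detect import LocalHit
from .contig_map import CloneMap, nonredundant_span
from .seqmodel import AnnotationTrack, GenomicInterval

CATEGORIES = ("wing_disc", "UTR", "embryonic_ns")

#: Known enhancer/UTR labels of the reference locus and their categories.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "sc-SOPE": "wing_disc",
    "L3/TSM": "wing_disc",
    "pTG": "wing_disc",
    "tr1-tr2": "wing_disc",
    "DCE": "wing_disc",
    "sc-UTR": "UTR",
    "l'sc-UTR": "UTR",
    "A": "embryonic_ns",
    "C": "embryonic_ns",
    "D": "embryonic_ns",
    "E": "embryonic_ns",
}


def _pct(part: float, total: float) -> float:
    if total == 0:
        return 0.0
    return float(Decimal(repr(100.0 * part / total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EnhancerOverlapReport:
    block_labels: list[list[str]]          # per block, enhancer labels
    block_categories: list[list[str]]      # per block, unique categories
    category_counts: Counter               # blocks per category (+ "none")
    multi_category_blocks: list[int] = field(default_factory=list)


def overlap_enhancers(blocks: list[LocalHit],
                      enhancer_track: AnnotationTrack,
                      category_map: dict[str, str] | None = None
                      ) -> EnhancerOverlapReport:
    """Label blocks with overlapping enhancers and count per category.

    A block gets every enhancer label it overlaps by >= 1 bp on the
    reference axis; category counts count blocks (once per category, a
    block in several categories is flagged), and blocks with no overlap
    count as "none".
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    trees: dict[str, IntervalTree] = {}
    for iv in enhancer_track:
        if iv.label not in cmap:
            raise ValueError(f"unknown enhancer label {iv.label!r}")
        trees.setdefault(iv.seq_id, IntervalTree()).addi(
            iv.start, iv.end, iv.label)
    labels: list[list[str]] = []
    cats: list[list[str]] = []
    counts: Counter = Counter()
    multi: list[int] = []
    for k, block in enumerate(blocks):
        iv = block.ref_interval
        tree = trees.get(iv.seq_id, IntervalTree())
        found = sorted({o.data for o in tree.overlap(iv.start, iv.end)})
        labels.append(found)
        bc = sorted({cmap[lbl] for lbl in found})
        cats.append(bc)
        if not bc:
            counts["none"] += 1
        else:
            for c in bc:
                counts[c] += 1
            if len(bc) > 1:
                multi.append(k)
    return EnhancerOverlapReport(block_labels=labels, block_categories=cats,
                                 category_counts=counts,
                                 multi_category_blocks=multi)


@dataclass
class BacSummaryRow:
    clone: str
    total_bp: int
    gene_count: int
    gene_bp: int
    gene_pct: float
    repeat_count: int
    repeat_bp: int
    repeat_pct: float


def bac_summary(clones: list[tuple[str, int]], gene_track: AnnotationTrack,
                repeat_track: AnnotationTrack,
                clone_map: CloneMap | None = None
                ) -> tuple[list[BacSummaryRow], BacSummaryRow,
                           BacSummaryRow | None]:
    """Per-clone gene/repeat content, a totals row and a nonredundant row.

    Tracks hold intervals on clone coordinate systems (seq_id = clone id).
    The nonredundant row (present when a clone map is given) uses the
    map's nonredundant span and counts each distinct gene label once.
    """
    rows = []
    for cid, length in clones:
        g = gene_track.for_seq(cid)
        r = repeat_track.for_seq(cid)
        gbp = sum(len(iv) for iv in g)
        rbp = sum(len(iv) for iv in r)
        rows.append(BacSummaryRow(
            clone=cid, total_bp=length, gene_count=len(g), gene_bp=gbp,
            gene_pct=_pct(gbp, length), repeat_count=len(r), repeat_bp=rbp,
            repeat_pct=_pct(rbp, length)))
    total_bp = sum(r.total_bp for r in rows)
    gene_bp = sum(r.gene_bp for r in rows)
    repeat_bp = sum(r.repeat_bp for r in rows)
    totals = BacSummaryRow(
        clone="Total", total_bp=total_bp,
        gene_count=sum(r.gene_count for r in rows), gene_bp=gene_bp,
        gene_pct=_pct(gene_bp, total_bp),
        repeat_count=sum(r.repeat_count for r in rows), repeat_bp=repeat_bp,
        repeat_pct=_pct(repeat_bp, total_bp))
    nonred = None
    if clone_map is not None:
        span = nonredundant_span(clone_map)
        by_label: dict[str, int] = {}
        for iv in gene_track:
            by_label.setdefault(iv.label, len(iv))
        nr_gene_bp = sum(by_label.values())
        nonred = BacSummaryRow(
            clone="Without overlap", total_bp=span,
            gene_count=len(by_label), gene_bp=nr_gene_bp,
            gene_pct=_pct(nr_gene_bp, span), repeat_count=0, repeat_bp=0,
            repeat_pct=0.0)
    return rows, totals, nonred


@dataclass(frozen=True)
class SizeEstimateInputs:
    ref_locus_bp: float
    ref_genome_bp: float
    query_genome_bp: float
    sequenced_bp: float
    covered_fraction: float

    def __post_init__(self) -> None:
        for v in (self.ref_locus_bp, self.ref_genome_bp,
                  self.query_genome_bp, self.sequenced_bp):
            if v <= 0:
                raise ValueError("size inputs must be positive")
        if not 0 < self.covered_fraction <= 1:
            raise ValueError("covered_fraction outside (0, 1]")


def scale_by_genome(inputs: SizeEstimateInputs) -> float:
    """Expected locus size under genome-size proportionality:
    ref_locus_bp * query_genome_bp / ref_genome_bp."""
    if inputs.ref_genome_bp == 0:
        raise ValueError("zero reference genome size")
    return inputs.ref_locus_bp * inputs.query_genome_bp \
        / inputs.ref_genome_bp


def extrapolate_by_coverage(sequenced_bp: float,
                            covered_fraction: float) -> float:
    """Locus-size estimate sequenced_bp / covered_fraction."""
    if not 0 < covered_fraction <= 1:
        raise ValueError("covered_fraction outside (0, 1]")
    return sequenced_bp / covered_fraction


def coverage_fraction(blocks: list[LocalHit],
                      ref_locus: GenomicInterval) -> float:
    """Fraction of the reference locus spanned by the conserved blocks:
    (max block end - min block start) / locus length, clipped to [0, 1]."""
    if not blocks:
        raise ValueError("empty block list")
    lo = min(b.ref_interval.start for b in blocks)
    hi = max(b.ref_interval.end for b in blocks)
    return min(1.0, max(0.0, (hi - lo) / len(ref_locus)))
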