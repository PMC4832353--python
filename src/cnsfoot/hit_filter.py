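"""Masking of coding/repeat hits and cross-validation against a second
reference species.

A local-alignment hit is explained by an annotation when most of its span
(in either species) lies inside the feature; such hits are discarded with a
reason, and every input hit is accounted for in the report.  Blocks found
against one reference are *recovered* when the comparison against a second
reference finds a block at the same query-side location.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .cns_detect import LocalHit
from .seqmodel import AnnotationTrack, GenomicInterval


@dataclass
class FilterReport:
    n_input: int
    n_coding_removed: int
    n_repeat_removed: int
    n_retained: int
    removed: list[tuple[LocalHit, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != (self.n_retained + self.n_coding_removed
                            + self.n_repeat_removed):
            raise ValueError("filter report does not account for all hits")


def _trees(track: AnnotationTrack | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if track is not None:
        for iv in track:
            trees.setdefault(iv.seq_id, IntervalTree()).addi(
                iv.start, iv.end)
    return trees


def _covered_fraction(iv: GenomicInterval,
                      trees: dict[str, IntervalTree]) -> float:
    tree = trees.get(iv.seq_id)
    if tree is None:
        return 0.0
    covered = 0
    merged: list[tuple[int, int]] = []
    for hit in sorted(tree.overlap(iv.start, iv.end)):
        s, e = max(hit.begin, iv.start), min(hit.end, iv.end)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    covered = sum(e - s for s, e in merged)
    return covered / len(iv)


def mask_hits(hits: list[LocalHit], coding_track: AnnotationTrack | None,
              repeat_track: AnnotationTrack | None,
              max_overlap_frac: float = 0.5
              ) -> tuple[list[LocalHit], FilterReport]:
    """Remove hits mostly covered by coding sequence or repeats.

    A hit is removed when the covered fraction of its reference OR query
    span exceeds ``max_overlap_frac``; coding takes precedence over repeat
    when both apply.  Idempotent, and retained + removed == input.
    """
    coding = _trees(coding_track)
    repeats = _trees(repeat_track)
    retained: list[LocalHit] = []
    removed: list[tuple[LocalHit, str]] = []
    for hit in hits:
        spans = (hit.ref_interval, hit.query_interval)
        if any(_covered_fraction(iv, coding) > max_overlap_frac
               for iv in spans):
            removed.append((hit, "coding"))
        elif any(_covered_fraction(iv, repeats) > max_overlap_frac
                 for iv in spans):
            removed.append((hit, "repeat"))
        else:
            retained.append(hit)
    report = FilterReport(
        n_input=len(hits),
        n_coding_removed=sum(1 for _, r in removed if r == "coding"),
        n_repeat_removed=sum(1 for _, r in removed if r == "repeat"),
        n_retained=len(retained),
        removed=removed)
    return retained, report


@dataclass
class ValidatedBlock:
    hit: LocalHit
    recovered: bool


def cross_validate(blocks_vs_ref1: list[LocalHit],
                   blocks_vs_ref2: list[LocalHit],
                   min_overlap_bp: int = 1) -> list[ValidatedBlock]:
    """Flag ref1 blocks recovered by the ref2 comparison.

    Both lists must use the same query-side coordinate system; a block is
    recovered iff some ref2 block's query interval overlaps its query
    interval by at least ``min_overlap_bp``.  Input order is preserved.
    """
    trees: dict[str, IntervalTree] = {}
    for other in blocks_vs_ref2:
        iv = other.query_interval
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for block in blocks_vs_ref1:
        iv = block.query_interval
        tree = trees.get(iv.seq_id)
        recovered = False
        if tree is not None:
            for o in tree.overlap(iv.start, iv.end):
                if min(o.end, iv.end) - max(o.begin, iv.start) \
                        >= min_overlap_bp:
                    recovered = True
                    break
        out.append(ValidatedBlock(hit=block, recovered=recovered))
    return out
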