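"""Projection of clone-local coordinates onto a single contig axis.

Sequenced BAC clones tile the locus with overlaps; anchor pairs (the same
position observed in two clone coordinate systems, e.g. a conserved block
present in two overlapping clones) fix the relative offsets.  Where several
anchors join the same clone pair, the offset is their least-squares (mean)
value; anchors disagreeing beyond ``tolerance`` raise an error.  Overlapping
clones may carry different alleles of the same region, so anchor spread at
the indel scale of allelic variation is expected and the tolerance must be
set accordingly.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Anchor:
    """One position seen in two clone coordinate systems (1 bp, 0-based)."""

    clone_a: str
    pos_a: int
    clone_b: str
    pos_b: int


@dataclass
class CloneMap:
    """Ordered clones with contig offsets and overlap accounting."""

    clones: list[tuple[str, int, float]]   # (id, length, contig offset)
    identical_overlap_bp: int = 0
    allelic_overlap_bp: int = 0
    abutted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        offsets = [off for _, _, off in self.clones]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("clone offsets must be strictly increasing")

    @property
    def offsets(self) -> dict[str, float]:
        return {cid: off for cid, _, off in self.clones}

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: ln for cid, ln, _ in self.clones}

    def project(self, clone: str, position: float) -> float:
        """Contig position of a clone-local position (order-preserving)."""
        offs = self.offsets
        if clone not in offs:
            raise KeyError(f"unknown clone {clone!r}")
        length = self.lengths[clone]
        if not 0 <= position <= length:
            raise ValueError(
                f"position {position} outside clone {clone} [0, {length}]")
        return offs[clone] + position


def build_clone_map(clones: list[tuple[str, int]], anchors: list[Anchor],
                    identical_overlap_bp: int = 0,
                    allelic_overlap_bp: int = 0,
                    tolerance: float = 10.0) -> CloneMap:
    """Offsets for an ordered clone list from overlap anchors.

    The first clone sits at offset 0.  For each consecutive pair, every
    anchor implies ``offset(B) = offset(A) + pos_a - pos_b``; implied
    offsets are averaged (least squares) and must agree within
    ``tolerance`` bp.  Pairs with no anchor are assumed to abut and are
    flagged in ``abutted_pairs``.
    """
    by_pair: dict[tuple[str, str], list[float]] = {}
    ids = [cid for cid, _ in clones]
    for a in anchors:
        if a.clone_a not in ids or a.clone_b not in ids:
            raise ValueError(f"anchor references unknown clone: {a}")
        by_pair.setdefault((a.clone_a, a.clone_b), []).append(
            float(a.pos_a - a.pos_b))
    out: list[tuple[str, int, float]] = []
    abutted: list[tuple[str, str]] = []
    offset = 0.0
    for k, (cid, length) in enumerate(clones):
        if k == 0:
            out.append((cid, length, 0.0))
            continue
        prev = clones[k - 1][0]
        deltas = by_pair.get((prev, cid), [])
        deltas += [-d for d in by_pair.get((cid, prev), [])]
        if deltas:
            if max(deltas) - min(deltas) > tolerance:
                raise ValueError(
                    f"anchors between {prev} and {cid} imply contradictory "
                    f"offsets {sorted(deltas)} (spread "
                    f"{max(deltas) - min(deltas):.0f} bp > tolerance "
                    f"{tolerance:g} bp)")
            delta = sum(deltas) / len(deltas)
        else:
            delta = float(clones[k - 1][1])
            abutted.append((prev, cid))
        offset += delta
        out.append((cid, length, offset))
    return CloneMap(clones=out, identical_overlap_bp=identical_overlap_bp,
                    allelic_overlap_bp=allelic_overlap_bp,
                    abutted_pairs=abutted)


def project(clone_map: CloneMap, clone: str, position: float) -> float:
    return clone_map.project(clone, position)


def nonredundant_span(clone_map: CloneMap) -> int:
    """Nonredundant bp = sum of clone lengths minus identical and allelic
    overlap."""
    total = sum(ln for _, ln, _ in clone_map.clones)
    span = total - clone_map.identical_overlap_bp \
        - clone_map.allelic_overlap_bp
    if span < 0:
        raise ValueError("overlaps exceed total clone length")
    return span
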