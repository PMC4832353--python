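"""Colinearity analysis of conserved blocks between two species.

Blocks are sorted by reference start and their query-side positions are
projected onto the clone contig axis; the maximal colinear chain is the
longest strictly increasing subsequence (LIS) of projected query midpoints
(midpoints make minus-strand blocks need no special casing).  Blocks
outside the chain are order breaks; breaks are further classified by rank
displacement — how many positions a block's query-order rank differs from
its reference-order rank — into *local shuffles* (microrearrangement
scale, displacement below the threshold) and *clear breaks* (long-range
relocations).  Orientation flips (minus-strand blocks) are microinversions
and never count against chain membership.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass

from .cns_detect import LocalHit
from .contig_map import CloneMap


@dataclass
class SyntenyChain:
    """A maximal colinear chain plus the blocks that fall outside it."""

    blocks: list[LocalHit]             # sorted by reference start
    positions: list[float]             # projected query contig positions
    chain_members: list[int]           # indices into blocks
    breaks: list[int]                  # indices into blocks
    clear_breaks: list[int]            # subset of breaks
    inversions: list[int]              # indices of '-' strand blocks

    @property
    def n_breaks(self) -> int:
        return len(self.breaks)

    @property
    def n_clear_breaks(self) -> int:
        return len(self.clear_breaks)


def longest_increasing_subsequence(values: list[float]) -> list[int]:
    """Indices of the longest strictly increasing subsequence, O(n log n).

    Among equal-length chains the lexicographically earliest index set is
    returned: suffix chain lengths come from a backward patience pass, then
    a greedy forward scan always takes the smallest admissible index.
    """
    n = len(values)
    if not n:
        return []
    # suffix[i] = length of the longest strictly increasing chain starting
    # at i.  Equivalent to LIS-ending-at on the reversed, negated sequence.
    suffix = [0] * n
    tails: list[float] = []
    for i in range(n - 1, -1, -1):
        v = -values[i]
        k = bisect.bisect_left(tails, v)
        suffix[i] = k + 1
        if k == len(tails):
            tails.append(v)
        else:
            tails[k] = v
    best = max(suffix)
    chain: list[int] = []
    need, last = best, float("-inf")
    for i in range(n):
        if suffix[i] == need and values[i] > last:
            chain.append(i)
            last = values[i]
            need -= 1
            if need == 0:
                break
    return chain


def chain_colinear(blocks: list[LocalHit], clone_map: CloneMap | None = None,
                   use: str = "midpoint",
                   clear_break_min_displacement: int = 5) -> SyntenyChain:
    """Partition blocks into a maximal colinear chain and order breaks.

    ``clone_map`` projects each block's query coordinate (clone-local) onto
    the contig; pass None when query coordinates already share one axis.
    ``use`` selects the query ordering statistic: midpoint (default),
    start or end.
    """
    if use not in ("midpoint", "start", "end"):
        raise ValueError(f"unknown ordering statistic {use!r}")
    order = sorted(range(len(blocks)),
                   key=lambda i: (blocks[i].ref_interval.start,
                                  blocks[i].query_interval.start))
    blocks = [blocks[i] for i in order]
    positions: list[float] = []
    for b in blocks:
        iv = b.query_interval
        local = {"midpoint": iv.midpoint, "start": float(iv.start),
                 "end": float(iv.end)}[use]
        if clone_map is not None:
            positions.append(clone_map.project(iv.seq_id, local))
        else:
            positions.append(local)
    chain = longest_increasing_subsequence(positions)
    in_chain = set(chain)
    breaks = [i for i in range(len(blocks)) if i not in in_chain]
    # rank displacement: |query-order rank - reference-order rank|
    qrank = {i: r for r, i in enumerate(
        sorted(range(len(blocks)), key=lambda i: positions[i]))}
    clear = [i for i in breaks
             if abs(qrank[i] - i) >= clear_break_min_displacement]
    inversions = [i for i, b in enumerate(blocks) if b.strand == "-"]
    return SyntenyChain(blocks=blocks, positions=positions,
                        chain_members=chain, breaks=breaks,
                        clear_breaks=clear, inversions=inversions)


def count_inversions(blocks: list[LocalHit]) -> int:
    """Number of minus-strand (orientation-flipped) blocks."""
    return sum(1 for b in blocks if b.strand == "-")
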