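"""IUPAC binding-site scanning and enhancer-architecture comparison.

Motifs are degenerate IUPAC consensi (E-box CANNTG, N-box CACNAG, ...).
The scanner reports every position/strand at which the consensus matches;
a window matching on both strands (self-reverse-complementary match) is
reported once with strand '.'.  Architectures — the ordered arrangement of
sites within an enhancer window — are compared by site counts and by
whether one ordered motif-name string is a subsequence of the other.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seqmodel import GenomicInterval, SequenceRecord, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Default motif dictionary.  E-box, N-box, En/Antp and Ara/Caup consensi
#: are anchored to the proneural-enhancer literature; the alpha-box and
#: beta-box consensi are not published and ship empty — supply them via
#: user configuration before scanning.  The Ara/Caup site (ACA) is too
#: short for locus-wide scanning and should only be counted within a
#: user-chosen window such as a conserved block.
DEFAULT_MOTIFS: dict[str, str] = {
    "E-box": "CANNTG",
    "N-box": "CACNAG",
    "EnAntp": "TTAATTAA",
    "AraCaup": "ACA",
    "TATA": "TATAWAW",
    "alpha-box": "",
    "beta-box": "",
}


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r} has an empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: invalid IUPAC symbol(s) {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.pattern)

    def revcomp_pattern(self) -> str:
        return self.pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    interval: GenomicInterval
    strand: str
    matched: str


@dataclass
class Architecture:
    """Ordered binding sites within an enhancer window."""

    window: GenomicInterval
    sites: list[tuple[str, int, str]]      # (motif name, offset, strand)
    counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.sites.sort(key=lambda s: (s[1], s[0]))
        expect = Counter(name for name, _, _ in self.sites)
        if not self.counts:
            self.counts = expect
        elif self.counts != expect:
            raise ValueError("counts inconsistent with site list")

    @property
    def name_string(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.sites)


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    for k, sym in enumerate(pattern):
        if seq[pos + k] not in IUPAC[sym]:
            return False
    return True


def default_motifs() -> list[Motif]:
    return [Motif(name, pat, "literature-default")
            for name, pat in DEFAULT_MOTIFS.items() if pat]


def scan_motifs(seq: SequenceRecord | str, motifs: list[Motif],
                seq_id: str | None = None) -> list[MotifHit]:
    """All matches of each motif on both strands, sorted by position.

    A minus-strand match at a window means the window's reverse complement
    satisfies the pattern — equivalently, the reverse-complemented pattern
    matches the forward sequence.  Windows matching on both strands are
    reported once with strand '.'.
    """
    if isinstance(seq, SequenceRecord):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq.upper(), seq_id or "seq"
    hits: list[MotifHit] = []
    for motif in motifs:
        fwd = motif.pattern.upper()
        rev = motif.revcomp_pattern()
        w = motif.width
        for i in range(len(residues) - w + 1):
            on_fwd = _matches_at(residues, fwd, i)
            on_rev = _matches_at(residues, rev, i)
            if not (on_fwd or on_rev):
                continue
            strand = "." if (on_fwd and on_rev) else ("+" if on_fwd else "-")
            hits.append(MotifHit(
                motif=motif.name,
                interval=GenomicInterval(sid, i, i + w,
                                         strand if strand != "." else ".",
                                         motif.name),
                strand=strand, matched=residues[i:i + w]))
    hits.sort(key=lambda h: (h.interval.start, h.motif, h.strand))
    return hits


def find_paired_sites(hits: list[MotifHit], motif_a: str, motif_b: str,
                      max_gap: int, max_overlap: int = 0
                      ) -> list[tuple[MotifHit, MotifHit, int]]:
    """Ordered adjacent/overlapping site pairs on one sequence.

    The gap is the distance between the upstream site's end and the
    downstream site's start; pairs with ``-max_overlap <= gap <= max_gap``
    are reported.  Symmetric in A/B: either motif may be upstream.
    """
    pairs = []
    a_hits = [h for h in hits if h.motif == motif_a]
    b_hits = [h for h in hits if h.motif == motif_b]
    seen = set()
    for ha in a_hits:
        for hb in b_hits:
            if ha is hb:
                continue
            first, second = (ha, hb) if ha.interval.start <= \
                hb.interval.start else (hb, ha)
            key = (id(first), id(second))
            if key in seen:
                continue
            gap = second.interval.start - first.interval.end
            if -max_overlap <= gap <= max_gap:
                seen.add(key)
                pairs.append((first, second, gap))
    pairs.sort(key=lambda p: (p[0].interval.start, p[1].interval.start))
    return pairs


def architecture(seq: SequenceRecord | str, window: GenomicInterval,
                 motifs: list[Motif]) -> Architecture:
    """Counts and ordered site list over a window of the sequence."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not 0 <= window.start < window.end <= len(residues):
        raise ValueError("window outside sequence bounds")
    sub = residues[window.start:window.end]
    hits = scan_motifs(sub, motifs, seq_id=window.seq_id)
    sites = [(h.motif, h.interval.start, h.strand) for h in hits]
    return Architecture(window=window, sites=sites)


@dataclass
class ArchitectureComparison:
    count_differences: dict[str, tuple[int, int]]
    lcs_length: int
    order_conserved: bool


def _lcs(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a)):
        for j in range(len(b)):
            dp[i + 1][j + 1] = dp[i][j] + 1 if a[i] == b[j] else \
                max(dp[i][j + 1], dp[i + 1][j])
    return dp[len(a)][len(b)]


def compare_architectures(a: Architecture, b: Architecture
                          ) -> ArchitectureComparison:
    """Count table, LCS of ordered motif names, and order-conservation.

    Order is conserved iff one ordered name string is a subsequence of the
    other (the LCS equals the shorter string).
    """
    names = set(a.counts) | set(b.counts)
    diffs = {n: (a.counts.get(n, 0), b.counts.get(n, 0)) for n in names}
    lcs = _lcs(a.name_string, b.name_string)
    order = lcs == min(len(a.name_string), len(b.name_string))
    return ArchitectureComparison(count_differences=diffs, lcs_length=lcs,
                                  order_conserved=order)
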