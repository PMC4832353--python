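"""Detection of short conserved blocks between two long sequences.

Two detectors are provided, mirroring the two classic approaches to
phylogenetic footprinting of fast-turnover noncoding DNA:

* :func:`local_align` — a seed-and-extend local aligner (exact word seeds,
  ungapped X-drop extension, gapped Smith–Waterman refinement) reporting
  hits with Karlin–Altschul e-values ``E = K·m·n·exp(-lambda·S)``.
* :func:`window_conserved_segments` — a windowed percent-identity caller
  over a fixed pairwise alignment (the VISTA-style criterion: every window
  of at least ``min_width`` columns at ``min_identity`` percent identity).

The statistics follow the classical ungapped local-alignment theory:
``lambda`` is the unique positive root of sum_ij p_i p_j exp(lambda s_ij) = 1
and ``K`` is evaluated by the partial-sum series over the associated random
walk.  Gapped hits reuse the ungapped parameters, a standard approximation;
no claim of bit-for-bit equality with any particular BLAST build is made.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.optimize import brentq

from .seqmodel import GenomicInterval, SequenceRecord, revcomp

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Scoring and Karlin–Altschul statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus the statistical parameters.

    ``background`` are the four nucleotide frequencies (A, C, G, T).
    ``lam`` and ``K`` are filled in by :func:`solve_karlin_altschul`.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lam: float | None = None
    K: float | None = None

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def p_match(self) -> float:
        return float(sum(p * p for p in self.background))

    @property
    def expected_pair_score(self) -> float:
        pm = self.p_match
        return pm * self.match + (1 - pm) * self.mismatch

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / LN2

    def evalue(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


def solve_karlin_altschul(scheme: ScoringScheme) -> ScoringScheme:
    """Fill in lambda and K of an ungapped match/mismatch scheme.

    lambda is found by bracketed root-finding on
    ``f(lam) = p_match·e^{lam·match} + (1-p_match)·e^{lam·mismatch} - 1``;
    K by the partial-sum series of the score random walk (scores first
    rescaled by their gcd so the walk lives on the unit lattice).
    """
    if scheme.expected_pair_score >= 0:
        raise ValueError("no positive root: expected pair score must be "
                         "negative")
    g = math.gcd(scheme.match, -scheme.mismatch)
    probs = {scheme.match // g: scheme.p_match,
             scheme.mismatch // g: 1.0 - scheme.p_match}

    def f(lam: float) -> float:
        return sum(p * math.exp(lam * s) for s, p in probs.items()) - 1.0

    # bracket the positive root: f(0)=0, f'(0)<0, f(+inf)=+inf
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam_scaled = brentq(f, 1e-12, hi, xtol=1e-15, rtol=1e-15)

    K = _karlin_K_series(probs, lam_scaled)
    return replace(scheme, lam=lam_scaled / g, K=K)


def _karlin_K_series(probs: dict[int, float], lam: float,
                     kmax: int = 500, tol: float = 1e-12) -> float:
    """K for an integer-score walk via the partial-sum series.

    sigma = sum_k (1/k) [ P(S_k >= 0) + E(e^{lam S_k}; S_k < 0) ] and
    K = exp(-2 sigma) / (av (1 - e^{-lam·delta})) with ``av`` the mean step
    of the associated (tilted) walk and ``delta`` the lattice span of the
    step support (1 after gcd rescaling).
    """
    scores = sorted(probs)
    lo, hi = scores[0], scores[-1]
    delta = 0
    for s in scores:
        delta = math.gcd(delta, abs(s))
    delta = delta or 1
    base = np.zeros(hi - lo + 1)
    for s, p in probs.items():
        base[s - lo] = p
    av = sum(p * math.exp(lam * s) * s for s, p in probs.items())
    sigma = 0.0
    cur = np.array([1.0])
    cur_lo = 0
    for k in range(1, kmax + 1):
        cur = np.convolve(cur, base)
        cur_lo += lo
        js = np.arange(cur_lo, cur_lo + len(cur))
        neg = js < 0
        inner = float(cur[~neg].sum()) + float(
            np.sum(cur[neg] * np.exp(lam * js[neg])))
        sigma += inner / k
        if inner / k < tol:
            break
    return math.exp(-2.0 * sigma) / (av * (1.0 - math.exp(-lam * delta)))


# ---------------------------------------------------------------------------
# Hits and alignment statistics
# ---------------------------------------------------------------------------

@dataclass
class LocalHit:
    """One conserved block: paired intervals plus alignment statistics."""

    ref_interval: GenomicInterval
    query_interval: GenomicInterval
    strand: str
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    footnote: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.pct_identity <= 100:
            raise ValueError("pct_identity outside (0, 100]")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class ConservedSegment:
    """A VISTA-style conserved window of a pairwise alignment."""

    ref_interval: GenomicInterval
    query_interval: GenomicInterval
    pct_identity: float
    width: int


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def hit_stats(columns: list[tuple[str, str]]
              ) -> tuple[float, int, int, int]:
    """(pct_identity, aln_length, mismatches, gap_opens) of aligned columns.

    ``columns`` are (ref_char, query_char) pairs with '-' for a gap.
    gap_opens counts maximal gap runs (in either row), not gap columns.
    """
    if not columns:
        raise ValueError("empty alignment")
    matches = mismatches = 0
    gap_opens = 0
    in_ref_gap = in_query_gap = False
    for a, b in columns:
        if a == "-":
            if not in_ref_gap:
                gap_opens += 1
            in_ref_gap, in_query_gap = True, False
        elif b == "-":
            if not in_query_gap:
                gap_opens += 1
            in_ref_gap, in_query_gap = False, True
        else:
            in_ref_gap = in_query_gap = False
            if a == b:
                matches += 1
            else:
                mismatches += 1
    length = len(columns)
    return _round2(100.0 * matches / length), length, mismatches, gap_opens


# ---------------------------------------------------------------------------
# Seed-and-extend local alignment
# ---------------------------------------------------------------------------

def local_align(query: SequenceRecord, subject: SequenceRecord,
                scheme: ScoringScheme, word_len: int = 7,
                xdrop: int = 20, evalue_max: float = 0.1,
                band: int = 16, pad: int = 25) -> list[LocalHit]:
    """Seed-and-extend local alignment of ``query`` against ``subject``.

    Exact ``word_len``-mers seed both strands; each seed is extended
    ungapped with an X-drop rule, promising candidates are refined by a
    gapped Smith–Waterman pass on a padded window, and hits at
    ``evalue <= evalue_max`` are reported (e-value on the full m·n search
    space).  A hit wholly contained in a higher-scoring hit within
    ``band`` diagonals is dropped.  Ties are broken by leftmost reference
    then leftmost query start.
    """
    if scheme.lam is None or scheme.K is None:
        raise ValueError("scoring scheme lacks lambda/K; "
                         "run solve_karlin_altschul first")
    if word_len < 4:
        raise ValueError("word_len must be >= 4")
    if not len(query) or not len(subject):
        raise ValueError("empty sequence")
    m, n = len(subject), len(query)
    # raw-score prefilter: gapped refinement can only raise a core's score,
    # so cores far below the e-value cutoff (50x slack) are dropped early
    s_min = max(
        word_len * scheme.match,
        int(math.floor((math.log(scheme.K * m * n)
                        - math.log(evalue_max * 50.0)) / scheme.lam)),
    )
    index = _word_index(subject.residues, word_len)

    raw_hits: list[LocalHit] = []
    for strand in "+-":
        q = query.residues if strand == "+" else revcomp(query.residues)
        cands = _merge_candidates(
            _candidates(q, subject.residues, index, word_len,
                        scheme, xdrop, s_min), band + pad)
        for (qs, qe, ss, se) in cands:
            hit = _gapped_hit(q, subject.residues, qs, qe, ss, se,
                              scheme, pad, m, n)
            if hit is None or hit[0] is None:
                continue
            score, s0, s1, q0, q1, cols = hit
            ev = scheme.evalue(score, m, n)
            if ev > evalue_max:
                continue
            pid, alen, mism, gaps = hit_stats(cols)
            if strand == "+":
                q_iv = GenomicInterval(query.id, q0, q1, "+")
            else:
                q_iv = GenomicInterval(query.id, n - q1, n - q0, "-")
            raw_hits.append(LocalHit(
                ref_interval=GenomicInterval(subject.id, s0, s1, "+"),
                query_interval=q_iv, strand=strand, raw_score=score,
                bit_score=round(scheme.bit_score(score), 1), evalue=ev,
                pct_identity=pid, aln_length=alen, mismatches=mism,
                gap_opens=gaps))
    return _dedup_hits(raw_hits, band)


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - w + 1):
        word = seq[j:j + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    return index


def _candidates(q: str, s: str, index: dict[str, list[int]], w: int,
                scheme: ScoringScheme, xdrop: int, s_min: int,
                ) -> list[tuple[int, int, int, int]]:
    """Ungapped X-drop extension of word seeds -> candidate segment pairs.

    Returns (q_start, q_end, s_start, s_end) of ungapped cores scoring at
    least ``s_min``.  Seeds falling inside a region already extended on the
    same diagonal are skipped.
    """
    match, mismatch = scheme.match, scheme.mismatch
    covered: dict[int, int] = {}   # diagonal -> q position extended through
    out = []
    nq, ns = len(q), len(s)
    for i in range(nq - w + 1):
        positions = index.get(q[i:i + w])
        if not positions:
            continue
        for j in positions:
            diag = i - j
            if covered.get(diag, -1) >= i:
                continue
            # extend right from seed start
            best = score = 0
            bi = i - 1
            k = 0
            while i + k < nq and j + k < ns:
                score += match if q[i + k] == s[j + k] else mismatch
                if score > best:
                    best, bi = score, i + k
                elif best - score > xdrop:
                    break
                k += 1
            right_end = bi + 1                      # exclusive, in q coords
            total = best
            # extend left from seed start
            best = score = 0
            bl = i
            k = 1
            while i - k >= 0 and j - k >= 0:
                score += match if q[i - k] == s[j - k] else mismatch
                if score > best:
                    best, bl = score, i - k
                elif best - score > xdrop:
                    break
                k += 1
            total += best
            covered[diag] = max(covered.get(diag, -1), right_end)
            if total >= s_min and right_end > bl:
                out.append((total, bl, right_end, bl - diag,
                            right_end - diag))
    return out


def _merge_candidates(cands: list[tuple[int, int, int, int, int]],
                      band: int) -> list[tuple[int, int, int, int]]:
    """Collapse ungapped cores that the same gapped window would refine.

    Cores are taken best-score first; a core contained (within ``band`` in
    both coordinates) in an already accepted core's window is dropped.
    """
    cands = sorted(cands, key=lambda c: (-c[0], c[1], c[3]))
    kept: list[tuple[int, int, int, int]] = []
    for _, qs, qe, ss, se in cands:
        redundant = False
        for kqs, kqe, kss, kse in kept:
            if (qs >= kqs - band and qe <= kqe + band
                    and ss >= kss - band and se <= kse + band):
                redundant = True
                break
        if not redundant:
            kept.append((qs, qe, ss, se))
    return kept


def _gapped_hit(q: str, s: str, qs: int, qe: int, ss: int, se: int,
                scheme: ScoringScheme, pad: int, m: int, n: int):
    """Gapped Smith–Waterman refinement on a padded window around an
    ungapped core.  Returns (score, s0, s1, q0, q1, columns)."""
    q0w, q1w = max(0, qs - pad), min(len(q), qe + pad)
    s0w, s1w = max(0, ss - pad), min(len(s), se + pad)
    sub_q, sub_s = q[q0w:q1w], s[s0w:s1w]
    score, (sa, sb, qa, qb), cols = smith_waterman(
        sub_s, sub_q, scheme)
    if score <= 0:
        return None
    return score, s0w + sa, s0w + sb, q0w + qa, q0w + qb, cols


def smith_waterman(ref: str, qry: str, scheme: ScoringScheme
                   ) -> tuple[int, tuple[int, int, int, int],
                              list[tuple[str, str]]]:
    """Affine-gap local alignment (Gotoh) with traceback.

    Returns (best score, (ref_start, ref_end, q_start, q_end), columns).
    Ties are resolved toward the smallest end coordinates and, during
    traceback, diagonal moves are preferred.
    """
    nr, nq = len(ref), len(qry)
    NEG = -10 ** 9
    H = [[0] * (nq + 1) for _ in range(nr + 1)]
    E = [[NEG] * (nq + 1) for _ in range(nr + 1)]  # gap in ref row
    F = [[NEG] * (nq + 1) for _ in range(nr + 1)]  # gap in qry row
    go, ge = scheme.gap_open, scheme.gap_extend
    ma, mi = scheme.match, scheme.mismatch
    best, bi, bj = 0, 0, 0
    for i in range(1, nr + 1):
        ri = ref[i - 1]
        Hi, Hm = H[i], H[i - 1]
        Ei, Fi, Fm = E[i], F[i], F[i - 1]
        for j in range(1, nq + 1):
            e = Ei[j - 1] + ge
            eo = Hi[j - 1] + go + ge
            if eo > e:
                e = eo
            f = Fm[j] + ge
            fo = Hm[j] + go + ge
            if fo > f:
                f = fo
            d = Hm[j - 1] + (ma if ri == qry[j - 1] else mi)
            h = d if d > 0 else 0
            if e > h:
                h = e
            if f > h:
                h = f
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return 0, (0, 0, 0, 0), []
    # traceback
    cols: list[tuple[str, str]] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            d = H[i - 1][j - 1] + (ma if ref[i - 1] == qry[j - 1] else mi)
            if H[i][j] == d:
                cols.append((ref[i - 1], qry[j - 1]))
                i, j = i - 1, j - 1
                continue
            state = "F" if H[i][j] == F[i][j] else "E"
        if state == "E":
            cols.append(("-", qry[j - 1]))
            opened = E[i][j] == H[i][j - 1] + go + ge
            j -= 1
            state = "H" if opened else "E"
        else:
            cols.append((ref[i - 1], "-"))
            opened = F[i][j] == H[i - 1][j] + go + ge
            i -= 1
            state = "H" if opened else "F"
    cols.reverse()
    return best, (i, bi, j, bj), cols


def _dedup_hits(hits: list[LocalHit], band: int) -> list[LocalHit]:
    """Drop hits contained in a higher-scoring hit on a nearby diagonal."""
    def diag(h: LocalHit) -> int:
        return h.query_interval.start - h.ref_interval.start

    order = sorted(hits, key=lambda h: (-h.raw_score,
                                        h.ref_interval.start,
                                        h.query_interval.start))
    kept: list[LocalHit] = []
    for h in order:
        contained = False
        for k in kept:
            if (k.strand == h.strand
                    and abs(diag(k) - diag(h)) <= band
                    and k.ref_interval.start <= h.ref_interval.start
                    and h.ref_interval.end <= k.ref_interval.end
                    and k.query_interval.start <= h.query_interval.start
                    and h.query_interval.end <= k.query_interval.end):
                contained = True
                break
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.ref_interval.start, h.query_interval.start))
    return kept


# ---------------------------------------------------------------------------
# Windowed-identity conserved segments (VISTA-style)
# ---------------------------------------------------------------------------

def conserved_column_mask(aln_ref: str, aln_query: str, min_width: int,
                          min_identity: float) -> np.ndarray:
    """Boolean mask over alignment columns covered by at least one
    qualifying window (length >= min_width, identity >= min_identity)."""
    if len(aln_ref) != len(aln_query):
        raise ValueError("aligned strings differ in length")
    L = len(aln_ref)
    in_union = np.zeros(L, dtype=bool)
    if min_width > L:
        return in_union
    a = np.frombuffer(aln_ref.encode(), dtype=np.uint8)
    b = np.frombuffer(aln_query.encode(), dtype=np.uint8)
    matches = ((a == b) & (a != ord("-"))).astype(np.int64)
    P = np.concatenate([[0], np.cumsum(matches)])
    for i in range(L - min_width + 1):
        lens = np.arange(min_width, L - i + 1)
        ok = 100.0 * (P[i + min_width:] - P[i]) >= min_identity * lens
        idx = np.nonzero(ok)[0]
        if len(idx):
            jmax = i + min_width + int(idx[-1])
            in_union[i:jmax] = True
    return in_union


def window_conserved_segments(aln_ref: str, aln_query: str,
                              min_width: int = 25,
                              min_identity: float = 85.0,
                              ref_id: str = "ref", query_id: str = "query",
                              ref_offset: int = 0, query_offset: int = 0,
                              ) -> list[ConservedSegment]:
    """Conserved windows of a pairwise alignment.

    A window is any run of >= ``min_width`` columns whose percent identity
    is >= ``min_identity`` (gap columns count as non-identities).  All
    qualifying windows are merged; each maximal merged run is reported with
    its overall identity and the ungapped coordinates it spans.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity outside (0, 100]")
    L = len(aln_ref)
    a = np.frombuffer(aln_ref.encode(), dtype=np.uint8)
    b = np.frombuffer(aln_query.encode(), dtype=np.uint8)
    in_union = conserved_column_mask(aln_ref, aln_query, min_width,
                                     min_identity)
    matches = ((a == b) & (a != ord("-"))).astype(np.int64)
    P = np.concatenate([[0], np.cumsum(matches)])
    segments = []
    ref_pos = np.concatenate([[0], np.cumsum(a != ord("-"))])
    qry_pos = np.concatenate([[0], np.cumsum(b != ord("-"))])
    i = 0
    while i < L:
        if not in_union[i]:
            i += 1
            continue
        j = i
        while j < L and in_union[j]:
            j += 1
        width = j - i
        ident = 100.0 * float(P[j] - P[i]) / width
        r0, r1 = int(ref_pos[i]), int(ref_pos[j])
        q0, q1 = int(qry_pos[i]), int(qry_pos[j])
        if r1 > r0 and q1 > q0:
            segments.append(ConservedSegment(
                ref_interval=GenomicInterval(
                    ref_id, ref_offset + r0, ref_offset + r1, "+"),
                query_interval=GenomicInterval(
                    query_id, query_offset + q0, query_offset + q1, "+"),
                pct_identity=_round2(ident), width=width))
        i = j
    return segments
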