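"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration, kept
deliberately naive and separate from the package implementation.
"""
from __future__ import annotations

from cnsfoot.motif_scan import IUPAC


def lis_length_exhaustive(values: list[float]) -> int:
    """Longest strictly increasing subsequence by enumerating all
    subsequences."""
    best = 0
    n = len(values)
    for mask in range(1, 2 ** n):
        sub = [values[i] for i in range(n) if mask >> i & 1]
        if all(a < b for a, b in zip(sub, sub[1:])):
            best = max(best, len(sub))
    return best


def window_union_mask(aln_ref: str, aln_query: str, min_width: int,
                      min_identity: float) -> list[bool]:
    """Union of all qualifying windows by enumerating every window."""
    L = len(aln_ref)
    m = [aln_ref[k] == aln_query[k] and aln_ref[k] != "-"
         for k in range(L)]
    out = [False] * L
    for i in range(L):
        for j in range(i + min_width, L + 1):
            if 100.0 * sum(m[i:j]) >= min_identity * (j - i):
                for k in range(i, j):
                    out[k] = True
    return out


def alignment_stats_percolumn(columns) -> tuple[float, int, int, int]:
    """Per-column scan: identity %, length, mismatches, maximal gap runs."""
    matches = mismatches = gaps = 0
    runs = 0
    prev_gap_row = None
    for a, b in columns:
        if a == "-" or b == "-":
            row = 0 if a == "-" else 1
            if row != prev_gap_row:
                runs += 1
            prev_gap_row = row
            gaps += 1
        else:
            prev_gap_row = None
            if a == b:
                matches += 1
            else:
                mismatches += 1
    length = len(columns)
    pct = round(100.0 * matches / length, 2)
    return pct, length, mismatches, runs


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def scan_iupac_bruteforce(seq: str, pattern: str
                          ) -> list[tuple[int, str]]:
    """All (position, strand) IUPAC matches by sliding a window on both
    strands; both-strand windows reported once with '.'."""
    w = len(pattern)
    out = []
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        fwd = all(window[k] in IUPAC[pattern[k]] for k in range(w))
        rc = _revcomp(window)
        rev = all(rc[k] in IUPAC[pattern[k]] for k in range(w))
        if fwd and rev:
            out.append((i, "."))
        elif fwd:
            out.append((i, "+"))
        elif rev:
            out.append((i, "-"))
    return out


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def covered_fraction_quadratic(start: int, end: int,
                               features: list[tuple[int, int]]) -> float:
    """Covered fraction of [start, end) by a feature set, per-base scan."""
    covered = 0
    for pos in range(start, end):
        if any(s <= pos < e for s, e in features):
            covered += 1
    return covered / (end - start)


def lcs_dp(a, b) -> int:
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a)):
        for j in range(len(b)):
            dp[i + 1][j + 1] = dp[i][j] + 1 if a[i] == b[j] else \
                max(dp[i][j + 1], dp[i + 1][j])
    return dp[len(a)][len(b)]
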