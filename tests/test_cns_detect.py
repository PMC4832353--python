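import math

import numpy as np
import pytest

import _oracles
from conftest import random_dna
from cnsfoot import (GenomicInterval, ScoringScheme, SequenceRecord,
                     local_align, revcomp, smith_waterman,
                     solve_karlin_altschul, window_conserved_segments)
from cnsfoot.cns_detect import conserved_column_mask, hit_stats


class TestKarlinAltschul:
    def test_lambda_closed_form(self):
        # +1/-1 uniform: 0.25 e^lam + 0.75 e^-lam = 1 has root e^lam = 3
        s = solve_karlin_altschul(ScoringScheme(match=1, mismatch=-1))
        assert s.lam == pytest.approx(math.log(3), abs=1e-9)

    @pytest.mark.parametrize("match,mismatch", [(1, -1), (1, -2), (2, -3),
                                                (1, -3), (3, -4)])
    def test_defining_equation_residual(self, match, mismatch):
        s = solve_karlin_altschul(ScoringScheme(match=match,
                                                mismatch=mismatch))
        pm = s.p_match
        resid = pm * math.exp(s.lam * match) \
            + (1 - pm) * math.exp(s.lam * mismatch) - 1.0
        assert abs(resid) < 1e-9
        assert s.K > 0

    def test_lambda_matches_bisection_oracle(self):
        s = solve_karlin_altschul(ScoringScheme(match=2, mismatch=-3))

        def f(lam):
            return 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1

        lo, hi = 1e-9, 5.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert s.lam == pytest.approx((lo + hi) / 2, abs=1e-6)

    @pytest.mark.parametrize("match,mismatch,expected_K", [
        # ungapped K values reported by NCBI blastn 2.17 for uniform
        # backgrounds, used as an independent reference implementation
        (1, -1, 0.333), (1, -2, 0.621), (2, -3, 0.408)])
    def test_K_matches_blastn_report(self, match, mismatch, expected_K):
        s = solve_karlin_altschul(ScoringScheme(match=match,
                                                mismatch=mismatch))
        assert s.K == pytest.approx(expected_K, abs=5e-4)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="no positive root"):
            solve_karlin_altschul(ScoringScheme(
                match=3, mismatch=-1,
                background=(0.25, 0.25, 0.25, 0.25)))

    def test_evalue_monotone_in_score_and_search_space(self,
                                                       default_scheme):
        s = default_scheme
        evs = [s.evalue(score, 1000, 1000) for score in range(5, 40)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert s.evalue(20, 1000, 1000) < s.evalue(20, 4000, 1000)


class TestHitStats:
    def test_perfect_match(self):
        cols = [("A", "A")] * 36
        assert hit_stats(cols) == (100.00, 36, 0, 0)

    def test_single_column(self):
        assert hit_stats([("G", "G")]) == (100.00, 1, 0, 0)

    def test_random_alignments_match_percolumn_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cols = []
            for _ in range(int(rng.integers(1, 120))):
                kind = rng.random()
                if kind < 0.1:
                    cols.append(("-", str(rng.choice(list("ACGT")))))
                elif kind < 0.2:
                    cols.append((str(rng.choice(list("ACGT"))), "-"))
                else:
                    cols.append((str(rng.choice(list("ACGT"))),
                                 str(rng.choice(list("ACGT")))))
            assert hit_stats(cols) == \
                _oracles.alignment_stats_percolumn(cols)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            hit_stats([])


class TestSmithWaterman:
    def test_scores_match_biopython_local_aligner(self, default_scheme):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = default_scheme.match
        aligner.mismatch_score = default_scheme.mismatch
        # Biopython charges open+extend for the first gap character
        aligner.open_gap_score = default_scheme.gap_open \
            + default_scheme.gap_extend
        aligner.extend_gap_score = default_scheme.gap_extend
        rng = np.random.default_rng(3)
        for _ in range(60):
            x = random_dna(rng, int(rng.integers(5, 60)))
            y = random_dna(rng, int(rng.integers(5, 60)))
            mine, _, cols = smith_waterman(x, y, default_scheme)
            assert mine == aligner.score(x, y)
            # traceback columns rescore to the reported score
            score = 0
            prev_gap = False
            for a, b in cols:
                if a == "-" or b == "-":
                    score += default_scheme.gap_extend
                    if not prev_gap:
                        score += default_scheme.gap_open
                    prev_gap = True
                else:
                    prev_gap = False
                    score += default_scheme.match if a == b \
                        else default_scheme.mismatch
            if cols:
                assert score == mine


class TestLocalAlign:
    def test_self_alignment_full_length(self, default_scheme):
        s = random_dna(np.random.default_rng(42), 500)
        hits = local_align(SequenceRecord("q", s), SequenceRecord("s", s),
                           default_scheme)
        top = max(hits, key=lambda h: h.raw_score)
        assert (top.ref_interval.start, top.ref_interval.end) == (0, 500)
        assert (top.query_interval.start, top.query_interval.end) == (0, 500)
        assert top.pct_identity == 100.0 and top.strand == "+"

    def test_planted_island_found_without_false_positives(
            self, default_scheme):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            island = random_dna(rng, 30)
            qa = random_dna(rng, 5000)
            sb = random_dna(rng, 5000)
            q = SequenceRecord("q", qa[:2000] + island + qa[2000:])
            s = SequenceRecord("s", sb[:3000] + island + sb[3000:])
            hits = local_align(q, s, default_scheme, evalue_max=0.1)
            on = [h for h in hits
                  if h.ref_interval.overlap(
                      GenomicInterval("s", 3000, 3030))
                  and h.query_interval.overlap(
                      GenomicInterval("q", 2000, 2030))]
            if on and len(on) == len(hits):
                clean += 1
        assert clean >= 18

    def test_strand_symmetry_under_subject_revcomp(self, default_scheme):
        rng = np.random.default_rng(5)
        island = random_dna(rng, 40)
        qa = random_dna(rng, 2000)
        sb = random_dna(rng, 2000)
        q = SequenceRecord("q", qa[:800] + island + qa[800:])
        fwd = sb[:1200] + island + sb[1200:]
        h1 = local_align(q, SequenceRecord("s", fwd), default_scheme)
        h2 = local_align(q, SequenceRecord("s", revcomp(fwd)),
                         default_scheme)
        n = len(fwd)
        as_tuples = {(h.ref_interval.start, h.ref_interval.end,
                      h.query_interval.start, h.query_interval.end,
                      h.strand) for h in h1}
        mirrored = {(n - h.ref_interval.end, n - h.ref_interval.start,
                     h.query_interval.start, h.query_interval.end,
                     "+" if h.strand == "-" else "-") for h in h2}
        assert as_tuples and as_tuples == mirrored

    def test_unsolved_scheme_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            local_align(SequenceRecord("q", "ACGT" * 10),
                        SequenceRecord("s", "ACGT" * 10), ScoringScheme())


class TestWindowConservedSegments:
    def test_fully_identical_alignment(self):
        s = random_dna(np.random.default_rng(1), 200)
        (seg,) = window_conserved_segments(s, s, 100, 70.0)
        assert seg.width == 200 and seg.pct_identity == 100.0
        assert (seg.ref_interval.start, seg.ref_interval.end) == (0, 200)

    def test_alternating_blocks_below_ceiling(self):
        # 10 matches / 10 mismatches alternating: no window reaches 95%
        ref = ("A" * 10 + "C" * 10) * 5
        qry = ("A" * 10 + "G" * 10) * 5
        assert window_conserved_segments(ref, qry, 15, 95.0) == []

    def test_min_width_longer_than_alignment(self):
        assert window_conserved_segments("ACGT", "ACGT", 10, 50.0) == []

    def test_mask_equals_all_windows_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            L = int(rng.integers(5, 300))
            ref = "".join(rng.choice(list("ACGT-"), size=L,
                                     p=[.23, .23, .23, .23, .08]))
            qry = "".join(rng.choice(list("ACGT-"), size=L,
                                     p=[.23, .23, .23, .23, .08]))
            for w, t in ((5, 80.0), (15, 60.0), (25, 85.0)):
                got = conserved_column_mask(ref, qry, w, t)
                assert got.tolist() == \
                    _oracles.window_union_mask(ref, qry, w, t)
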