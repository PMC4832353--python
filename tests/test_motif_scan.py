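import numpy as np
import pytest

import _oracles
from conftest import random_dna
from cnsfoot import (Architecture, GenomicInterval, Motif, architecture,
                     compare_architectures, find_paired_sites, revcomp,
                     scan_motifs)


EBOX = Motif("E-box", "CANNTG")
NBOX = Motif("N-box", "CACNAG")
ENANTP = Motif("EnAntp", "TTAATTAA")


class TestScanMotifs:
    def test_direct_ebox_match(self):
        hits = scan_motifs("ACAGGTGA", [EBOX])
        # CAGGTG at offset 1; CANNTG also matches its reverse complement
        on_fwd = [h for h in hits if h.interval.start == 1]
        assert len(on_fwd) == 1
        assert on_fwd[0].matched == "CAGGTG"

    def test_palindrome_reported_once_unstranded(self):
        hits = scan_motifs("GGG" + "TTAATTAA" + "CCC", [ENANTP])
        assert len(hits) == 1
        assert hits[0].strand == "." and hits[0].interval.start == 3

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            Motif("bad", "ACGX")
        with pytest.raises(ValueError, match="empty"):
            Motif("empty", "")

    @pytest.mark.parametrize("motif", [EBOX, NBOX, ENANTP,
                                       Motif("TATA", "TATAWAW")])
    def test_matches_sliding_window_oracle(self, motif):
        rng = np.random.default_rng(hash(motif.name) % 2**31)
        for _ in range(25):
            seq = random_dna(rng, 1000)
            got = [(h.interval.start, h.strand)
                   for h in scan_motifs(seq, [motif])]
            assert got == _oracles.scan_iupac_bruteforce(seq, motif.pattern)

    def test_revcomp_sequence_mirrors_hits(self):
        rng = np.random.default_rng(77)
        seq = random_dna(rng, 500)
        fwd = scan_motifs(seq, [EBOX, NBOX])
        rev = scan_motifs(revcomp(seq), [EBOX, NBOX])
        n = len(seq)

        def key(hits, mirror):
            out = set()
            for h in hits:
                if mirror:
                    start = n - h.interval.end
                    strand = {"+": "-", "-": "+", ".": "."}[h.strand]
                else:
                    start, strand = h.interval.start, h.strand
                out.add((h.motif, start, strand))
            return out

        assert key(fwd, False) == key(rev, True)

    def test_expected_hit_count_on_uniform_sequence(self):
        # non-palindromic width-w pattern: ~2 (L-w+1) 4^-w hits expected
        motif = Motif("probe", "ACGTAC")
        L, w = 2000, 6
        expect = 2 * (L - w + 1) * 4.0 ** -w
        counts = []
        rng = np.random.default_rng(123)
        for _ in range(100):
            counts.append(len(scan_motifs(random_dna(rng, L), [motif])))
        mean = float(np.mean(counts))
        se = float(np.std(counts, ddof=1)) / np.sqrt(len(counts))
        assert abs(mean - expect) <= 3 * max(se, 1e-9) + 1e-9


class TestPairedSites:
    def test_adjacent_ebox_nbox_gap_one(self):
        # E-box ending at 16, N-box starting at 17: the paired-site
        # configuration of the conserved proneural-enhancer core
        seq = "G" * 10 + "CAGGTG" + "A" + "CACGAG" + "G" * 10
        hits = scan_motifs(seq, [EBOX, NBOX])
        pairs = find_paired_sites(hits, "E-box", "N-box", max_gap=5)
        assert any(p[0].interval.end == 16 and p[1].interval.start == 17
                   and p[2] == 1 for p in pairs)

    def test_distant_sites_not_paired(self):
        seq = "CAGGTG" + "G" * 100 + "CACGAG"
        hits = scan_motifs(seq, [EBOX, NBOX])
        assert find_paired_sites(hits, "E-box", "N-box", max_gap=5) == []

    def test_random_hit_sets_match_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            seq = random_dna(rng, 400)
            hits = scan_motifs(seq, [EBOX, NBOX])
            pairs = find_paired_sites(hits, "E-box", "N-box", max_gap=10,
                                      max_overlap=3)
            expected = set()
            e_hits = [h for h in hits if h.motif == "E-box"]
            n_hits = [h for h in hits if h.motif == "N-box"]
            for ha in e_hits:
                for hb in n_hits:
                    first, second = (ha, hb) if ha.interval.start <= \
                        hb.interval.start else (hb, ha)
                    gap = second.interval.start - first.interval.end
                    if -3 <= gap <= 10:
                        expected.add((first.interval.start,
                                      second.interval.start))
            got = {(p[0].interval.start, p[1].interval.start)
                   for p in pairs}
            assert got == expected


class TestArchitecture:
    def test_empty_window(self):
        arch = architecture("A" * 100, GenomicInterval("s", 10, 60),
                            [EBOX, NBOX])
        assert arch.sites == [] and not arch.counts

    def test_synthetic_sope_counts(self):
        # 4 E-boxes, 1 N-box, 2 alpha-boxes, 1 beta-box planted in order
        alpha = Motif("alpha-box", "GGGAATTCCC")
        beta = Motif("beta-box", "CGCGCAAGGG")
        spacer = "TTTTT"
        parts = ["CAGCTG", "GGGAATTCCC", "CACGAG", "CATATG", "CGCGCAAGGG",
                 "CATTTG", "GGGAATTCCC", "CAACTG"]
        seq = "TT" + spacer.join(parts) + "TT"
        arch = architecture(seq, GenomicInterval("s", 0, len(seq)),
                            [EBOX, NBOX, alpha, beta])
        assert arch.counts["E-box"] == 4
        assert arch.counts["N-box"] == 1
        assert arch.counts["alpha-box"] == 2
        assert arch.counts["beta-box"] == 1

    def test_deterministic_rescan(self):
        rng = np.random.default_rng(31)
        seq = random_dna(rng, 800)
        w = GenomicInterval("s", 100, 700)
        a1 = architecture(seq, w, [EBOX, NBOX])
        a2 = architecture(seq, w, [EBOX, NBOX])
        assert a1.sites == a2.sites and a1.counts == a2.counts

    def test_window_out_of_bounds(self):
        with pytest.raises(ValueError):
            architecture("ACGT" * 10, GenomicInterval("s", 30, 50), [EBOX])


class TestCompareArchitectures:
    def arch(self, names):
        return Architecture(
            window=GenomicInterval("s", 0, 1000),
            sites=[(n, i * 10, "+") for i, n in enumerate(names)])

    def test_identical_architectures_conserved(self):
        a = self.arch(["E-box", "N-box", "E-box"])
        cmp = compare_architectures(a, self.arch(
            ["E-box", "N-box", "E-box"]))
        assert cmp.order_conserved
        assert all(x == y for x, y in cmp.count_differences.values())

    def test_reordered_sites_not_conserved(self):
        cmp = compare_architectures(
            self.arch(["E-box", "N-box", "E-box"]),
            self.arch(["E-box", "E-box", "N-box"]))
        assert not cmp.order_conserved

    def test_subsequence_counts_as_conserved(self):
        cmp = compare_architectures(
            self.arch(["E-box", "N-box"]),
            self.arch(["E-box", "alpha-box", "N-box", "E-box"]))
        assert cmp.order_conserved

    def test_lcs_matches_dp_oracle(self):
        rng = np.random.default_rng(41)
        names = ["E-box", "N-box", "alpha-box", "beta-box"]
        for _ in range(50):
            a = [names[i] for i in rng.integers(0, 4,
                                                int(rng.integers(0, 10)))]
            b = [names[i] for i in rng.integers(0, 4,
                                                int(rng.integers(0, 10)))]
            cmp = compare_architectures(self.arch(a), self.arch(b))
            assert cmp.lcs_length == _oracles.lcs_dp(tuple(a), tuple(b))
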