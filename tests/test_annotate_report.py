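import numpy as np
import pytest

import _oracles
from cnsfoot import (AnnotationTrack, GenomicInterval, LocalHit,
                     SizeEstimateInputs, bac_summary, coverage_fraction,
                     extrapolate_by_coverage, overlap_enhancers,
                     scale_by_genome)
from cnsfoot import fixtures


def make_block(seq, start, end):
    return LocalHit(ref_interval=GenomicInterval(seq, start, end),
                    query_interval=GenomicInterval("q", start, end),
                    strand="+", raw_score=10, bit_score=20.0, evalue=0.01,
                    pct_identity=90.0, aln_length=end - start,
                    mismatches=0, gap_opens=0)


class TestOverlapEnhancers:
    def test_empty_track_all_none(self):
        blocks = [make_block("dmel", 10, 40), make_block("dmel", 50, 90)]
        report = overlap_enhancers(
            blocks, AnnotationTrack("empty", "enhancer"))
        assert report.category_counts == {"none": 2}

    def test_fixture_wing_disc_count(self):
        report = overlap_enhancers(fixtures.table2_hits(),
                                   fixtures.enhancer_track(),
                                   fixtures.category_map())
        assert report.category_counts["wing_disc"] == 7
        assert report.category_counts["UTR"] == 2
        assert report.category_counts["embryonic_ns"] == 9
        assert report.category_counts["none"] == 10

    def test_unknown_label_rejected(self):
        track = AnnotationTrack("t", "enhancer")
        track.intervals = [GenomicInterval("dmel", 0, 10, ".", "mystery")]
        with pytest.raises(ValueError, match="mystery"):
            overlap_enhancers([make_block("dmel", 0, 5)], track)

    def test_random_blocks_match_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        labels = ["sc-SOPE", "pTG", "A", "C", "sc-UTR"]
        track = AnnotationTrack("t", "enhancer")
        for k in range(30):
            s = int(rng.integers(0, 5000))
            track.intervals.append(GenomicInterval(
                "dmel", s, s + int(rng.integers(20, 200)), ".",
                labels[int(rng.integers(len(labels)))]))
        blocks = []
        for _ in range(60):
            s = int(rng.integers(0, 5000))
            blocks.append(make_block("dmel", s, s + int(
                rng.integers(10, 100))))
        report = overlap_enhancers(blocks, track)
        for block, got in zip(blocks, report.block_labels):
            expected = sorted({
                iv.label for iv in track.intervals
                if _oracles.overlap_bp(block.ref_interval.start,
                                       block.ref_interval.end,
                                       iv.start, iv.end) > 0})
            assert got == expected


class TestBacSummary:
    def test_published_clone_table_totals(self):
        clones, genes, repeats = fixtures.table1_tracks()
        rows, totals, nonred = bac_summary(clones, genes, repeats,
                                           clone_map=fixtures.clone_map())
        assert totals.total_bp == 651_394
        assert totals.gene_count == 5 and totals.gene_bp == 4_482
        assert totals.gene_pct == 0.69
        assert totals.repeat_count == 355
        assert totals.repeat_bp == 165_646
        assert totals.repeat_pct == 25.43
        assert nonred.gene_bp == 2_634        # ac + sc + l'sc once each
        assert nonred.gene_count == 3
        assert nonred.total_bp == 529_566
        assert nonred.gene_pct == 0.50

    def test_clone_without_annotations_zeroed(self):
        rows, totals, _ = bac_summary(
            [("X", 1000)], AnnotationTrack("g", "coding"),
            AnnotationTrack("r", "repeat"))
        assert rows[0].gene_count == 0 and rows[0].repeat_bp == 0
        assert rows[0].gene_pct == 0.0

    def test_totals_equal_column_sums_random_inputs(self):
        rng = np.random.default_rng(23)
        clones = [(f"c{i}", int(rng.integers(5000, 20000)))
                  for i in range(4)]
        genes = AnnotationTrack("g", "coding")
        repeats = AnnotationTrack("r", "repeat")
        for cid, length in clones:
            for k in range(int(rng.integers(0, 5))):
                s = int(rng.integers(0, length - 600))
                genes.intervals.append(GenomicInterval(
                    cid, s, s + int(rng.integers(100, 500)), "+",
                    f"{cid}_g{k}"))
            for k in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, length - 600))
                repeats.intervals.append(GenomicInterval(
                    cid, s, s + int(rng.integers(50, 400)), "+",
                    f"{cid}_r{k}"))
        rows, totals, _ = bac_summary(clones, genes, repeats)
        assert totals.gene_bp == sum(r.gene_bp for r in rows)
        assert totals.repeat_bp == sum(r.repeat_bp for r in rows)
        assert totals.gene_count == sum(r.gene_count for r in rows)


class TestSizeEstimates:
    def inputs(self):
        return SizeEstimateInputs(
            ref_locus_bp=104_000, ref_genome_bp=176e6,
            query_genome_bp=750e6, sequenced_bp=530_000,
            covered_fraction=0.78)

    def test_genome_scaling_estimate(self):
        # 104 kb x 750 Mb / 176 Mb
        assert scale_by_genome(self.inputs()) == \
            pytest.approx(443_181.8, abs=100)

    def test_equal_genomes_identity(self):
        inputs = SizeEstimateInputs(104_000, 176e6, 176e6, 1, 1.0)
        assert scale_by_genome(inputs) == 104_000

    def test_linearity_in_genome_size(self):
        a = self.inputs()
        b = SizeEstimateInputs(a.ref_locus_bp, a.ref_genome_bp,
                               2 * a.query_genome_bp, a.sequenced_bp,
                               a.covered_fraction)
        assert scale_by_genome(b) == pytest.approx(2 * scale_by_genome(a))

    def test_coverage_extrapolation(self):
        assert extrapolate_by_coverage(530_000, 0.78) == \
            pytest.approx(679_487.2, abs=10)
        assert extrapolate_by_coverage(1000, 1.0) == 1000
        assert extrapolate_by_coverage(1000, 0.25) == \
            2 * extrapolate_by_coverage(1000, 0.5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_by_coverage(1000, 0.0)
        with pytest.raises(ValueError):
            extrapolate_by_coverage(1000, 1.2)


class TestCoverageFraction:
    def test_full_span(self):
        locus = GenomicInterval("dmel", 0, 1000)
        blocks = [make_block("dmel", 0, 100), make_block("dmel", 900, 1000)]
        assert coverage_fraction(blocks, locus) == 1.0

    def test_single_central_block(self):
        locus = GenomicInterval("dmel", 0, 1000)
        assert coverage_fraction([make_block("dmel", 450, 550)], locus) \
            == pytest.approx(0.1)

    def test_fixture_span_near_published_fraction(self):
        frac = coverage_fraction(fixtures.table2_hits(),
                                 fixtures.REF_LOCUS)
        # (109 997 - 13 423) / 120 000; qualitatively the published ~78%
        assert frac == pytest.approx((109_997 - 13_422) / 120_000,
                                     abs=1e-6)
        assert 0.75 <= frac <= 0.85

    def test_empty_blocks_rejected(self):
        with pytest.raises(ValueError):
            coverage_fraction([], GenomicInterval("dmel", 0, 100))
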