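from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.segments import (
    SegmentBlock,
    assign_block_origin,
    call_deviation_blocks,
    detect_copy_number_blocks,
    downsample_counts,
    evaluate_recovery,
    refine_borders,
    segment_overlap,
)

from conftest import make_counts, make_track
from oracles import brute_force_blocks

MB = 1_000_000


class TestCallDeviationBlocks:
    def test_single_run(self):
        track = make_track([0.1, 0.1, 0.1, 1.0, 1.0, 1.0])
        blocks = call_deviation_blocks(track)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (0, 3 * MB)
        assert blocks[0].support_fraction == 1.0

    def test_merged_block_below_fraction_discarded(self):
        # two 5-window runs, 3-window gap at 1.0: merged 13 windows, 10/13 < 0.8
        devs = [0.1] * 5 + [1.0] * 3 + [0.1] * 5 + [1.0] * 5
        assert call_deviation_blocks(make_track(devs)) == []

    def test_merged_block_above_fraction_kept(self):
        # two 20-window runs, 3-window gap: 40/43 = 0.930 kept
        devs = [0.1] * 20 + [1.0] * 3 + [0.1] * 20 + [1.0] * 5
        blocks = call_deviation_blocks(make_track(devs))
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (0, 43 * MB)
        assert blocks[0].support_fraction == pytest.approx(40 / 43)

    def test_gap_beyond_merge_distance_stays_separate(self):
        devs = [0.1] * 5 + [1.0] * 6 + [0.1] * 5
        blocks = call_deviation_blocks(make_track(devs))
        assert [(b.start, b.end) for b in blocks] == [(0, 5 * MB), (11 * MB, 16 * MB)]

    def test_zygosity_from_mean_deviation(self):
        hom = call_deviation_blocks(make_track([0.05] * 5 + [1.0] * 10))[0]
        het = call_deviation_blocks(make_track([0.5] * 5 + [1.0] * 10))[0]
        assert hom.zygosity == "homozygous"
        assert het.zygosity == "heterozygous_or_monosomic"

    def test_undefined_windows_are_not_constituents(self):
        devs = [0.1, np.nan, 0.1, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        blocks = call_deviation_blocks(make_track(devs))
        assert len(blocks) == 1
        assert blocks[0].support_fraction == 1.0  # 2 below / 2 defined

    def test_chromosome_order_independence(self):
        devs_a = [0.1] * 4 + [1.0] * 10
        devs_b = [1.0] * 6 + [0.2] * 6 + [1.0] * 2
        t = pd.concat(
            [make_track(devs_a, chrom="c1"), make_track(devs_b, chrom="c2")],
            ignore_index=True,
        )
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = call_deviation_blocks(t)
        b = call_deviation_blocks(shuffled)
        assert [(x.chrom, x.start, x.end) for x in a] == [
            (x.chrom, x.start, x.end) for x in b
        ]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            devs = rng.choice(
                [0.0, 0.1, 0.5, 0.65, 0.7, 0.75, 1.0, 2.0, np.nan],
                size=n,
                p=[0.1, 0.15, 0.1, 0.1, 0.05, 0.05, 0.35, 0.05, 0.05],
            )
            expected = brute_force_blocks(list(devs))
            got = call_deviation_blocks(make_track(devs))
            assert [(b.start // MB, b.end // MB) for b in got] == expected


class TestAssignOrigin:
    def _profile(self, hom, het):
        grid = make_track([0.0] * len(hom))[["chrom", "start", "end"]]
        grid["hom"] = hom
        grid["het"] = het
        return grid

    def _block(self, n, zygosity="homozygous"):
        return SegmentBlock("chr1A", 0, n * MB, zygosity=zygosity)

    def test_hom_snps_with_high_ratio_assign_introgression(self):
        block = assign_block_origin(self._block(3), self._profile([50, 50, 50], [1, 1, 1]))
        assert block.origin == "donor_introgression"

    def test_zero_hom_matches_assign_deletion(self):
        block = assign_block_origin(self._block(3), self._profile([0, 0, 0], [2, 0, 1]))
        assert block.origin == "deletion"

    def test_low_hom_het_ratio_assigns_deletion(self):
        # plenty of hom matches but hom:het 0.5 -> aberrant mapping signature
        block = assign_block_origin(self._block(3), self._profile([50, 50, 50], [100, 100, 100]))
        assert block.origin == "deletion"

    def test_het_block_uses_total_density(self):
        het_block = assign_block_origin(
            self._block(2, "heterozygous_or_monosomic"), self._profile([0, 0], [200, 200])
        )
        assert het_block.origin == "donor_introgression"
        monosomic = assign_block_origin(
            self._block(2, "heterozygous_or_monosomic"), self._profile([0, 0], [10, 10])
        )
        assert monosomic.origin == "deletion"


class TestRefineBorders:
    def _fine(self, devs, start=0):
        return make_track(devs, width=100_000, start=start)

    def test_border_extends_outward(self):
        # coarse block [1,2] Mbp; fine windows < 0.7 back to 0.7 Mbp
        devs = [1.0] * 7 + [0.1] * 3 + [0.1] * 10 + [1.0] * 10
        block = SegmentBlock("chr1A", 1 * MB, 2 * MB)
        refined = refine_borders(block, self._fine(devs))
        assert refined.start == 700_000
        assert refined.end == 2 * MB

    def test_border_retracts_inward(self):
        # fine windows inside the left edge >= 0.7 up to 1.4 Mbp
        devs = [1.0] * 10 + [1.0] * 4 + [0.1] * 6 + [1.0] * 10
        block = SegmentBlock("chr1A", 1 * MB, 2 * MB)
        refined = refine_borders(block, self._fine(devs))
        assert refined.start == 1_400_000

    def test_missing_fine_coverage_skips_refinement(self):
        block = SegmentBlock("chr1A", 5 * MB, 6 * MB)
        refined = refine_borders(block, self._fine([0.1] * 5))
        assert (refined.start, refined.end) == (block.start, block.end)

    def test_subwindow_truth_boundary_recovered_within_one_fine_window(self):
        """Planted boundary off the 1 Mbp grid is recovered to within 100 kbp."""
        from introscan.simulate import PlantedEvent, SimConfig, simulate_line
        from introscan.workflow import detect_line

        cfg = SimConfig(
            events=(PlantedEvent("chr1D", 10_350_000, 30_000_000, "introgression", "hom"),),
            seed=7,
        )
        ds = simulate_line(cfg)
        blocks = [b for b in detect_line(ds) if b.origin == "donor_introgression"]
        assert len(blocks) == 1
        assert abs(blocks[0].start - 10_350_000) <= 100_000
        assert abs(blocks[0].end - 30_000_000) <= 100_000


class TestCopyNumberBlocks:
    def test_duplication_run(self):
        devs = [1.0] * 5 + [2.0] * 150 + [1.0] * 5
        blocks = detect_copy_number_blocks(make_track(devs))
        dups = [b for b in blocks if b.origin == "duplication"]
        assert len(dups) == 1
        assert dups[0].end - dups[0].start == 150 * MB

    def test_monosomic_band_run(self):
        devs = [1.0] * 5 + [0.5] * 40 + [1.0] * 5
        blocks = detect_copy_number_blocks(make_track(devs))
        assert len(blocks) == 1
        assert blocks[0].zygosity == "heterozygous_or_monosomic"

    def test_normal_track_yields_no_blocks(self):
        assert detect_copy_number_blocks(make_track([1.0] * 50)) == []


class TestDownsample:
    def test_fraction_one_is_identity(self):
        table = make_counts([10, 20, 30])
        out = downsample_counts(table, 1.0, seed=1)
        pd.testing.assert_frame_equal(out.frame, table.frame)
        assert out.total_reads == table.total_reads

    def test_binomial_moments(self):
        table = make_counts([1000] * 1000)
        out = downsample_counts(table, 0.5, seed=2)
        mean = out.frame["count"].mean()
        se = np.sqrt(1000 * 0.25 / 1000)
        assert abs(mean - 500) < 3 * se

    def test_deterministic_per_seed(self):
        table = make_counts([100] * 50)
        a = downsample_counts(table, 0.3, seed=9)
        b = downsample_counts(table, 0.3, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            downsample_counts(make_counts([1]), fraction, seed=0)


class TestEvaluateRecovery:
    TRUTH = [
        SegmentBlock("c1", 0, 10 * MB, origin="donor_introgression"),
        SegmentBlock("c2", 5 * MB, 20 * MB, origin="deletion"),
    ]

    def test_perfect_calls(self):
        res = evaluate_recovery(self.TRUTH, list(self.TRUTH))
        assert res.precision == res.recall == 1.0
        assert res.mean_boundary_error == 0.0

    def test_no_calls_zero_recall(self):
        res = evaluate_recovery(self.TRUTH, [])
        assert res.recall == 0.0

    def test_partial_recall(self):
        res = evaluate_recovery(self.TRUTH, [self.TRUTH[0]])
        assert res.recall == 0.5 and res.precision == 1.0

    def test_origin_mismatch_not_matched_unless_ignored(self):
        call = SegmentBlock("c1", 0, 10 * MB, origin="deletion")
        assert evaluate_recovery([self.TRUTH[0]], [call]).recall == 0.0
        assert evaluate_recovery([self.TRUTH[0]], [call], match_origin=False).recall == 1.0

    def test_reciprocal_overlap_requirement(self):
        # call covers truth but is 3x its size: overlap < 50% of the call
        call = SegmentBlock("c1", 0, 30 * MB, origin="donor_introgression")
        assert evaluate_recovery([self.TRUTH[0]], [call]).recall == 0.0


class TestSegmentOverlap:
    def test_partially_overlapping_lines(self):
        # overlapping 5D segments: shared region and a 10.9 Mbp unique region
        a = SegmentBlock("chr5D", 533_200_000, 566_100_000)
        b = SegmentBlock("chr5D", 544_100_000, 566_100_000)
        shared, ua, ub = segment_overlap(a, b)
        assert shared == ("chr5D", 544_100_000, 566_100_000)
        assert ua == [("chr5D", 533_200_000, 544_100_000)]
        assert ua[0][2] - ua[0][1] == 10_900_000
        assert ub == []

    def test_identical_intervals(self):
        a = SegmentBlock("c1", 0, 5)
        shared, ua, ub = segment_overlap(a, SegmentBlock("c1", 0, 5))
        assert shared == ("c1", 0, 5) and ua == [] and ub == []

    def test_disjoint_and_cross_chromosome(self):
        a = SegmentBlock("c1", 0, 5)
        assert segment_overlap(a, SegmentBlock("c1", 10, 20))[0] is None
        shared, ua, ub = segment_overlap(a, SegmentBlock("c2", 0, 5))
        assert shared is None and ua and ub
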