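from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.expression import (
    bin_by_identity,
    classify_de,
    expression_state,
    fisher_two_tailed,
    gene_status,
    merge_orthologue_counts,
    partition_de,
    select_triad_sets,
    t_test_two_tailed,
    triad_balance_test,
    windowed_lfc_profile,
)
from introscan.segments import SegmentBlock

from conftest import make_track
from oracles import exact_fisher_two_sided

MB = 1_000_000


class TestExpressionState:
    def test_mean_above_threshold_expressed(self):
        tpm = pd.DataFrame({"r1": [0.5], "r2": [1.5], "r3": [2.0]}, index=["g"])
        assert expression_state(tpm).iloc[0]

    def test_mean_exactly_at_threshold_not_expressed(self):
        tpm = pd.DataFrame({"r1": [1.0], "r2": [1.0], "r3": [1.0]}, index=["g"])
        assert not expression_state(tpm).iloc[0]

    def test_all_zero_not_expressed(self):
        tpm = pd.DataFrame({"r1": [0.0], "r2": [0.0]}, index=["g"])
        assert not expression_state(tpm).iloc[0]


class TestBinByIdentity:
    def test_top_bin_fraction(self):
        ident = pd.Series({"a": 99.5, "b": 99.5})
        expressed = pd.Series({"a": True, "b": False})
        out = bin_by_identity(ident, expressed)
        assert out.set_index("bin").loc[">=99", "fraction_expressed"] == 0.5

    def test_empty_bin_is_nan(self):
        ident = pd.Series({"a": 99.5})
        out = bin_by_identity(ident, pd.Series({"a": True}))
        assert np.isnan(out.set_index("bin").loc["[90,95)", "fraction_expressed"])

    def test_no_hit_lands_in_lowest_bin(self):
        ident = pd.Series({"a": np.nan})
        out = bin_by_identity(ident, pd.Series({"a": False}))
        assert out.set_index("bin").loc["<90", "n_genes"] == 1


class TestMergeOrthologueCounts:
    SEGMENTS = [SegmentBlock("chr5D", 0, 10 * MB, origin="donor_introgression")]
    POSITIONS = pd.DataFrame(
        {"gene": ["w1", "w2", "w3"], "chrom": ["chr5D"] * 3,
         "start": [1 * MB, 2 * MB, 20 * MB]}
    )
    PAIRS = pd.DataFrame({"donor_gene": ["d1"], "wheat_gene": ["w1"], "identity": [95.0]})

    def _counts(self):
        return pd.DataFrame(
            {"s1": [0, 5, 7, 10], "s2": [0, 6, 8, 12], "s3": [0, 7, 9, 8]},
            index=pd.Index(["w1", "w2", "w3", "d1"], name="gene"),
        )

    def test_merge_sums_counts_and_removes_donor_row(self):
        out = merge_orthologue_counts(self._counts(), self.POSITIONS, self.SEGMENTS, self.PAIRS)
        assert out.loc["w1"].tolist() == [10, 12, 8]
        assert "d1" not in out.index

    def test_unpaired_wheat_gene_in_segment_dropped(self):
        out = merge_orthologue_counts(self._counts(), self.POSITIONS, self.SEGMENTS, self.PAIRS)
        assert "w2" not in out.index

    def test_gene_outside_segments_unchanged(self):
        out = merge_orthologue_counts(self._counts(), self.POSITIONS, self.SEGMENTS, self.PAIRS)
        assert out.loc["w3"].tolist() == [7, 8, 9]

    def test_integer_count_sums_conserved_for_retained_genes(self):
        counts = self._counts()
        out = merge_orthologue_counts(counts, self.POSITIONS, self.SEGMENTS, self.PAIRS)
        retained_parts = counts.drop(index=["w2"])  # only the unpaired gene is removed
        assert out.to_numpy().sum() == retained_parts.to_numpy().sum()
        assert out.to_numpy().dtype.kind == "i"


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "comparison", "log2fc", "padj"])


class TestClassifyDE:
    def test_up_in_both_comparisons(self):
        de = de_frame([("g", "c1", 1.5, 0.01), ("g", "c2", 2.0, 0.001)])
        assert classify_de(de).loc["g"] == "up"

    def test_second_comparison_fails_magnitude(self):
        de = de_frame([("g", "c1", 1.5, 0.01), ("g", "c2", 0.9, 0.001)])
        assert classify_de(de).loc["g"] == "not_de"

    def test_sign_conflict_is_not_de(self):
        de = de_frame([("g", "c1", 1.5, 0.01), ("g", "c2", -1.5, 0.01)])
        assert classify_de(de).loc["g"] == "not_de"

    def test_padj_boundary_excluded(self):
        de = de_frame([("g", "c1", 1.5, 0.05), ("g", "c2", 1.5, 0.01)])
        assert classify_de(de).loc["g"] == "not_de"

    def test_missing_comparison_rejected(self):
        de = de_frame([("g", "c1", 1.5, 0.01), ("h", "c1", 1.0, 0.2), ("h", "c2", 1.0, 0.2)])
        with pytest.raises(ValueError):
            classify_de(de)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            for c in ("c1", "c2"):
                rows.append((f"g{i}", c, float(rng.normal(0, 2)), float(rng.uniform(0, 0.2))))
        de = de_frame(rows)
        n_prev = None
        for lfc_min in (0.5, 1.0, 1.5, 2.0):
            n = int((classify_de(de, lfc_min=lfc_min) != "not_de").sum())
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        n_prev = None
        for padj_max in (0.2, 0.1, 0.05, 0.01):
            n = int((classify_de(de, padj_max=padj_max) != "not_de").sum())
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestPartitionAndStatus:
    SEGMENTS = [
        SegmentBlock("c1", 0, 10 * MB, origin="donor_introgression"),
        SegmentBlock("c1", 20 * MB, 30 * MB, origin="deletion"),
    ]
    TRACK = make_track([0.05] * 10 + [1.0] * 10 + [0.05] * 10 + [0.5] * 10, chrom="c1")

    def test_partition(self):
        genes = pd.DataFrame(
            {"gene": ["a", "b", "c"], "chrom": ["c1"] * 3,
             "start": [5 * MB, 15 * MB, 35 * MB]}
        )
        region = partition_de(genes, self.SEGMENTS, self.TRACK)
        assert region.tolist() == ["introgressed", "background", "excluded"]

    def test_status(self):
        genes = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"], "chrom": ["c1"] * 4,
             "start": [5 * MB, 15 * MB, 25 * MB, 35 * MB]}
        )
        status = gene_status(genes, self.SEGMENTS, self.TRACK)
        assert status.tolist() == ["introgressed", "normal", "deleted", "other"]


class TestSelectTriads:
    TRIADS = pd.DataFrame(
        {"A": ["a1", "a2", "a3", "a4"], "B": ["b1", "b2", "b3", "b4"],
         "D": ["d1", "d2", "d3", "d4"]}
    )
    STATUS = pd.Series(
        {"a1": "normal", "b1": "normal", "d1": "introgressed",
         "a2": "normal", "b2": "other", "d2": "normal",
         "a3": "normal", "b3": "normal", "d3": "normal",
         "a4": "normal", "b4": "normal", "d4": "deleted"}
    )
    CALLS = pd.Series({"d1": "down", "d3": "not_de"})

    def _counts(self, low=None):
        genes = list(self.STATUS.index)
        frame = pd.DataFrame(5.0, index=genes, columns=["s1", "s2"])
        if low:
            frame.loc[low] = 0.1
        return frame

    def test_down_introgressed_d_is_test_triad(self):
        test, control = select_triad_sets(self.TRIADS, self.STATUS, self.CALLS, self._counts())
        assert "d1" in set(test["D"])

    def test_deleted_d_counts_as_downregulated(self):
        test, _ = select_triad_sets(self.TRIADS, self.STATUS, self.CALLS, self._counts())
        assert "d4" in set(test["D"])

    def test_non_normal_ab_excluded_from_both(self):
        test, control = select_triad_sets(self.TRIADS, self.STATUS, self.CALLS, self._counts())
        assert "d2" not in set(test["D"]) | set(control["D"])

    def test_normal_not_de_d_is_control(self):
        _, control = select_triad_sets(self.TRIADS, self.STATUS, self.CALLS, self._counts())
        assert set(control["D"]) == {"d3"}

    def test_low_expression_excluded(self):
        test, _ = select_triad_sets(
            self.TRIADS, self.STATUS, self.CALLS, self._counts(low="a1")
        )
        assert "d1" not in set(test["D"])


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(31)
        tables = [[[0, 74], [17, 86]], [[6, 88], [37, 69]], [[0, 0], [0, 0]]]
        for _ in range(150):
            n = int(rng.integers(1, 201))
            a = rng.multinomial(n, [0.25, 0.25, 0.25, 0.25])
            tables.append([[int(a[0]), int(a[1])], [int(a[2]), int(a[3])]])
        for t in tables:
            assert fisher_two_tailed(t) == pytest.approx(
                exact_fisher_two_sided(t), abs=1e-9
            )

    def test_row_and_column_swap_invariance(self):
        t = [[3, 10], [8, 2]]
        p = fisher_two_tailed(t)
        assert fisher_two_tailed([t[1], t[0]]) == pytest.approx(p)
        assert fisher_two_tailed([[3, 10][::-1], [8, 2][::-1]]) == pytest.approx(
            fisher_two_tailed([[10, 3], [2, 8]])
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed([[1, -1], [0, 2]])


class TestTTest:
    def test_identical_groups_give_one(self):
        assert t_test_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_shuffled_copy_gives_one(self):
        x = [0.3, -1.2, 2.2, 0.9]
        assert t_test_two_tailed(x, [2.2, 0.3, 0.9, -1.2]) == pytest.approx(1.0)

    def test_separated_normals_give_tiny_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        y = rng.normal(1, 1, 500)
        assert t_test_two_tailed(x, y) < 1e-10

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_tailed([1.0], [1.0, 2.0])


class TestTriadBalance:
    def test_null_simulation_shows_no_balancing(self, small_sim_config):
        """End-to-end triad analysis on simulated data where A/B homoeologues
        are untouched: the Fisher test must not report compensation."""
        from introscan.simulate import simulate_expression

        ds = simulate_expression(small_sim_config)
        de = pd.concat(ds.de_tables.values(), ignore_index=True)
        calls = classify_de(de)
        status = gene_status(ds.gene_positions, ds.segments, ds.dev_track)
        merged_counts = merge_orthologue_counts(
            ds.counts, ds.gene_positions, ds.segments, ds.pairs
        )
        test, control = select_triad_sets(ds.triads, status, calls, merged_counts)
        assert len(test) >= 5
        assert len(control) >= 20
        # every counts-eligible deleted-D triad must land in the test set
        deleted = set(ds.truth.loc[ds.truth["status_D"] == "deleted", "gene_D"])
        assert deleted & set(test["D"])
        lfc = de.groupby("gene")["log2fc"].mean()
        result = triad_balance_test(test, control, calls, lfc)
        assert result.table[0][0] == 0  # no upregulated homoeologues planted
        assert result.fisher_p > 0.05
        assert result.t_p > 1e-4


class TestWindowedLfc:
    GENES = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(6)], "chrom": ["c1"] * 6,
         "start": [i * 5 * MB for i in range(6)]}
    )

    def test_identical_means_give_zero(self):
        means = pd.Series(10.0, index=self.GENES["gene"])
        out = windowed_lfc_profile(means, means, self.GENES, {"c1": 30 * MB})
        covered = out["n_genes"] > 0
        assert np.allclose(out.loc[covered, "mean_log2fc"], 0.0)

    def test_deleted_region_is_strongly_negative(self):
        line = pd.Series([0.0] * 2 + [10.0] * 4, index=self.GENES["gene"])
        parent = pd.Series(10.0, index=self.GENES["gene"])
        out = windowed_lfc_profile(line, parent, self.GENES, {"c1": 30 * MB})
        assert out["mean_log2fc"].iloc[0] < -3

    def test_empty_window_is_nan(self):
        means = pd.Series(10.0, index=self.GENES["gene"])
        out = windowed_lfc_profile(means, means, self.GENES, {"c1": 40 * MB})
        assert np.isnan(out["mean_log2fc"].iloc[-1])
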