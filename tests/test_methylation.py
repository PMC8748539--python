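import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retroscope.methylation import (
    age_category,
    age_category_means,
    beta_to_m,
    group_compare_wilcoxon,
    map_probes_to_windows,
    region_priority_label,
    select_full_length_line1,
    subfamily_sample_means,
    te_tss_windows,
)
from retroscope.model import ProbeRecord, RepeatElement, RepeatSet, TEFamily


class TestBetaToM:
    def test_analytic_triple(self):
        assert beta_to_m(0.5) == pytest.approx(0.0, abs=1e-12)
        assert beta_to_m(0.8) == pytest.approx(2.0, abs=1e-12)
        assert beta_to_m(0.2) == pytest.approx(-2.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                beta_to_m(bad)

    @given(st.floats(1e-6, 1 - 1e-6))
    def test_antisymmetric_and_increasing(self, b):
        assert beta_to_m(1 - b) == pytest.approx(-beta_to_m(b), abs=1e-9)
        eps = 1e-7
        if b + eps < 1:
            assert beta_to_m(b + eps) > beta_to_m(b)

    def test_dataframe_shape_preserved(self):
        df = pd.DataFrame([[0.5, 0.8]], index=["cg1"], columns=["s1", "s2"])
        out = beta_to_m(df)
        assert list(out.loc["cg1"]) == pytest.approx([0.0, 2.0])


class TestFullLengthSelection:
    def test_length_threshold_boundaries(self):
        reps = RepeatSet(
            [
                RepeatElement("chr1", 0, 6000, "+", "L1HS"),
                RepeatElement("chr1", 10_000, 15_899, "+", "L1PA2"),
                RepeatElement("chr1", 20_000, 26_000, "+", "AluYa5"),
            ]
        )
        out = select_full_length_line1(reps, 5900)
        assert [el.subfamily for el in out] == ["L1HS"]  # 5899 bp and Alu excluded


class TestTSSWindows:
    def test_plus_strand_window_at_start(self):
        el = RepeatElement("chr1", 10_000, 16_000, "+", "L1HS")
        w = te_tss_windows([el], 500)[0]
        assert (w.start, w.end) == (9_500, 10_500)

    def test_minus_strand_window_at_end(self):
        el = RepeatElement("chr1", 10_000, 16_000, "-", "L1HS")
        w = te_tss_windows([el], 500)[0]
        assert (w.start, w.end) == (15_500, 16_500)

    def test_clamped_window_flagged(self):
        el = RepeatElement("chr1", 100, 400, "+", "AluYa5")
        w = te_tss_windows([el], 500, chrom_sizes={"chr1": 1000})[0]
        assert (w.start, w.end) == (0, 600)
        assert w.truncated


class TestProbeMapping:
    def _windows(self):
        alu = [
            RepeatElement("chr1", 10_000, 10_300, "+", "AluYb8"),
            RepeatElement("chr1", 10_600, 10_900, "+", "AluSx"),
            RepeatElement("chr1", 50_000, 50_300, "+", "AluYb8"),
            RepeatElement("chr1", 50_400, 50_700, "+", "AluYb8"),
        ]
        line1 = [RepeatElement("chr1", 100_000, 106_200, "+", "L1HS")]
        return (
            te_tss_windows(alu, 500),
            te_tss_windows(line1, 500),
        )

    def test_unique_assignment(self):
        alu_w, l1_w = self._windows()
        probes = [ProbeRecord("cgA", "chr1", 9_700)]
        assigned, excluded = map_probes_to_windows(probes, alu_w, l1_w)
        assert assigned.iloc[0].tolist() == ["cgA", "ALU", "AluYb8"]
        assert excluded.empty

    def test_multi_subfamily_excluded(self):
        alu_w, l1_w = self._windows()
        # 10,300 lies in both the AluYb8 and AluSx windows
        probes = [ProbeRecord("cgB", "chr1", 10_301)]
        _, excluded = map_probes_to_windows(probes, alu_w, l1_w)
        assert excluded.iloc[0].tolist() == ["cgB", "multi_subfamily"]

    def test_same_subfamily_overlap_still_assigned(self):
        alu_w, l1_w = self._windows()
        # 50,350 is inside windows of BOTH AluYb8 elements
        probes = [ProbeRecord("cgC", "chr1", 50_351)]
        assigned, excluded = map_probes_to_windows(probes, alu_w, l1_w)
        assert assigned.iloc[0]["subfamily"] == "AluYb8"
        assert excluded.empty

    def test_cross_family_excluded_and_partition(self):
        alu = te_tss_windows(
            [RepeatElement("chr1", 100_000, 100_300, "+", "AluSx")], 500
        )
        l1 = te_tss_windows(
            [RepeatElement("chr1", 100_200, 106_400, "+", "L1HS")], 500
        )
        probes = [
            ProbeRecord("cgX", "chr1", 100_100),
            ProbeRecord("cgFar", "chr1", 500_000),
        ]
        assigned, excluded = map_probes_to_windows(probes, alu, l1)
        assert excluded.iloc[0].tolist() == ["cgX", "cross_family"]
        n_unassigned = len(probes) - len(assigned) - len(excluded)
        assert (len(assigned), len(excluded), n_unassigned) == (0, 1, 1)


class TestAggregation:
    def test_subfamily_means(self):
        assignments = pd.DataFrame(
            {
                "probe_id": ["cg1", "cg2", "cg3"],
                "family": ["ALU"] * 3,
                "subfamily": ["AluYa5", "AluYa5", "AluSx"],
            }
        )
        m = pd.DataFrame(
            {"s1": [-2.0, 2.0, 1.5]}, index=["cg1", "cg2", "cg3"]
        )
        means = subfamily_sample_means(assignments, m)
        assert means.loc["AluYa5", "s1"] == 0.0
        assert means.loc["AluSx", "s1"] == 1.5

    def test_missing_probe_rejected(self):
        assignments = pd.DataFrame(
            {"probe_id": ["cgZ"], "family": ["ALU"], "subfamily": ["AluYa5"]}
        )
        with pytest.raises(ValueError, match="cgZ"):
            subfamily_sample_means(assignments, pd.DataFrame({"s1": []}))

    def test_age_categories(self):
        assert age_category("L1HS", TEFamily.LINE1) == "young"
        assert age_category("L1PA2", TEFamily.LINE1) == "young"
        assert age_category("L1PB1", TEFamily.LINE1) == "intermediate"
        assert age_category("L1M5", TEFamily.LINE1) == "old"
        assert age_category("AluYb8", TEFamily.ALU) == "young"
        assert age_category("AluSx", TEFamily.ALU) == "intermediate"
        assert age_category("AluJb", TEFamily.ALU) == "old"
        with pytest.raises(ValueError, match="XYZ"):
            age_category("XYZ", TEFamily.LINE1)
        with pytest.raises(ValueError):
            age_category("SVA_D", TEFamily.SVA)

    def test_age_means_invariant_to_subfamily_order(self):
        means = pd.DataFrame(
            {"s1": [1.0, 3.0, 5.0]}, index=["AluYa5", "AluYb8", "AluSx"]
        )
        a = age_category_means(means, TEFamily.ALU)
        b = age_category_means(means.iloc[::-1], TEFamily.ALU)
        pd.testing.assert_frame_equal(a, b)
        assert a.loc["young", "s1"] == 2.0  # unweighted mean of subfamily means


class TestRegionPriority:
    @pytest.mark.parametrize(
        "regions,expected",
        [
            (["Body", "TSS1500"], "TSS1500"),
            (["3UTR"], "3UTR"),
            (["TSS200", "5UTR", "Body"], "TSS200"),
        ],
    )
    def test_priority(self, regions, expected):
        assert region_priority_label(regions) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_priority_label([])


class TestWilcoxon:
    def test_exact_most_extreme_ranking(self):
        # all of b above all of a: 2/C(6,3) = 2/20 = 0.1 two-sided
        out = group_compare_wilcoxon([1, 2, 3], [4, 5, 6])
        assert out["p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_constant_groups(self):
        out = group_compare_wilcoxon([2.0, 2.0], [2.0, 2.0, 2.0])
        assert out["p_value"] == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        assert group_compare_wilcoxon(a, b)["p_value"] == pytest.approx(
            group_compare_wilcoxon(b, a)["p_value"]
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare_wilcoxon([], [1.0])
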