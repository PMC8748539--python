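import numpy as np
import pandas as pd
import pytest

from retroscope.model import ClinicalRecord
from retroscope.simulate import SimParams, simulate_clinical
from retroscope.survival import (
    dummy_encode,
    fit_cox_efs,
    km_logrank_by_burden,
    spearman_matrix,
    standardize_features,
)


class TestStandardize:
    def test_unit_variance_column(self):
        out = standardize_features(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert list(out["x"]) == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(size=20)})
        once = standardize_features(df)
        twice = standardize_features(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_column_dropped(self, caplog):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with caplog.at_level("WARNING"):
            out = standardize_features(df)
        assert list(out.columns) == ["x"]
        assert "constant" in caplog.text

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            standardize_features(pd.DataFrame({"x": [1.0]}))

    def test_dummy_reference_is_most_frequent(self):
        s = pd.Series(["a", "a", "b", "c", "a"])
        out = dummy_encode(s, "site")
        assert set(out.columns) == {"site_b", "site_c"}


class TestSpearman:
    def test_perfectly_monotone(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 25, 70], "z": [4, 3, 2, 1]})
        rho, p, sig = spearman_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho.values, rho.values.T)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        rho1, _, _ = spearman_matrix(df)
        df2 = df.copy()
        df2["a"] = np.exp(df2["a"])  # strictly increasing transform
        rho2, _, _ = spearman_matrix(df2)
        pd.testing.assert_frame_equal(rho1, rho2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1, 2], "y": [3, 4]}))


def _clinical(times, events, pids=None):
    pids = pids or [f"P{i}" for i in range(len(times))]
    return [
        ClinicalRecord(pid, t, e, 15.0, "localized", "leg")
        for pid, t, e in zip(pids, times, events)
    ]


class TestCox:
    def test_recovers_planted_coefficient(self):
        params = SimParams(burden_log_hazard=-0.7, censoring_rate=0.2)
        rng = np.random.default_rng(123)
        burdens = {f"P{i:04d}": int(b) for i, b in enumerate(rng.gamma(4, 20, 200))}
        clinical = simulate_clinical(burdens, params, rng)
        feats = standardize_features(
            pd.DataFrame(
                {"burden": pd.Series({p: float(b) for p, b in burdens.items()})}
            )
        )
        fit = fit_cox_efs(feats, clinical)
        coef = fit.table.loc["burden", "coef"]
        se = fit.table.loc["burden", "se"]
        assert abs(coef - (-0.7)) < 3 * se
        assert fit.lrt_statistic >= 0
        assert fit.lrt_df == 1
        assert (fit.table["HR"] > 0).all()

    def test_requires_an_event(self):
        clinical = _clinical([10, 20], [0, 0])
        feats = pd.DataFrame({"x": [0.1, -0.1]}, index=["P0", "P1"])
        with pytest.raises(ValueError, match="event"):
            fit_cox_efs(feats, clinical)


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [3.0, 5.0, 8.0, 11.0]
        events = [1, 1, 0, 1]
        clinical = _clinical(times + times, events + events)
        burdens = {f"P{i}": (200 if i < 4 else 10) for i in range(8)}
        out = km_logrank_by_burden(clinical, burdens, 100)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hand_computed_six_subject_ledger(self):
        """Risk-table ledger: high={1+,3,5}, low={2,4,6+} gives
        O-E = 4/15 and V = 866/900, so chi2 = 64/866."""
        clinical = _clinical([1, 3, 5, 2, 4, 6], [0, 1, 1, 1, 1, 0])
        burdens = {"P0": 150, "P1": 150, "P2": 150, "P3": 50, "P4": 50, "P5": 50}
        out = km_logrank_by_burden(clinical, burdens, 100)
        assert out["statistic"] == pytest.approx(64 / 866, rel=1e-9)
        from scipy import stats

        assert out["p_value"] == pytest.approx(stats.chi2.sf(64 / 866, 1), rel=1e-9)

    def test_burden_exactly_at_threshold_goes_low(self):
        clinical = _clinical([1, 2, 3, 4], [1, 1, 1, 1])
        burdens = {"P0": 100, "P1": 100, "P2": 101, "P3": 102}
        out = km_logrank_by_burden(clinical, burdens, 100)
        assert out["n_high"] == 2 and out["n_low"] == 2

    def test_empty_group_suggests_new_threshold(self):
        clinical = _clinical([1, 2], [1, 1])
        with pytest.raises(ValueError, match="threshold"):
            km_logrank_by_burden(clinical, {"P0": 10, "P1": 20}, 100)

    def test_curves_are_nonincreasing_from_one(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(100, 30).round(1) + 1
        events = (rng.random(30) < 0.8).astype(int)
        clinical = _clinical(list(times), list(events))
        burdens = {f"P{i}": (150 if i % 2 else 10) for i in range(30)}
        out = km_logrank_by_burden(clinical, burdens, 100)
        for curve in out["curves"].values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()
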