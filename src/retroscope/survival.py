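"""TE activity versus patient outcome.

Builds the per-patient feature matrix (insertion burden, TE expression
and TE-promoter methylation by evolutionary age, clinical covariates),
standardizes it, computes the Spearman correlation structure, fits an
event-free-survival Cox proportional-hazards model (Efron tie handling,
likelihood-ratio test against the null model), and stratifies
Kaplan-Meier curves at an insertion-burden threshold with a two-group
log-rank test.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .model import ClinicalRecord, CoxFit

logger = logging.getLogger(__name__)


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / SD with SD on n-1 denominator.

    Constant columns carry no information and are dropped with a warning.
    """
    if len(matrix) < 2:
        raise ValueError("standardization requires at least 2 rows")
    out = {}
    for col in matrix.columns:
        x = matrix[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            logger.warning("dropping constant feature column %r", col)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=matrix.index)


def dummy_encode(series: pd.Series, prefix: str) -> pd.DataFrame:
    """One-hot encode with the most frequent level as the reference."""
    counts = series.value_counts()
    reference = counts.index[0]
    levels = [lv for lv in counts.index if lv != reference]
    return pd.DataFrame(
        {f"{prefix}_{lv}": (series == lv).astype(float) for lv in levels},
        index=series.index,
    )


def spearman_matrix(
    features: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho with t-approximation p-values (df = n - 2).

    Returns ``(rho, p, significant)``; rho is symmetric with unit
    diagonal, and ``significant`` masks p < alpha off the diagonal.
    """
    n = len(features)
    if n < 3:
        raise ValueError(f"Spearman correlation requires >= 3 rows, got {n}")
    cols = list(features.columns)
    k = len(cols)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.spearmanr(features[cols[i]], features[cols[j]])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pmat, index=cols, columns=cols)
    sig = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return rho_df, p_df, sig


def _clinical_frame(clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "efs_time": [r.efs_time for r in clinical],
            "event": [r.event for r in clinical],
        },
        index=pd.Index([r.patient_id for r in clinical], name="patient_id"),
    )


def fit_cox_efs(
    features: pd.DataFrame, clinical: Sequence[ClinicalRecord]
) -> CoxFit:
    """Cox proportional-hazards fit of event-free survival on the features.

    Complete cases only; Efron handling for tied event times; the global
    p-value comes from the likelihood-ratio test against the null model
    with df equal to the number of fitted coefficients.
    """
    surv = _clinical_frame(clinical)
    df = features.join(surv, how="inner").dropna()
    if df.empty or int(df["event"].sum()) < 1:
        raise ValueError("Cox fit requires at least one observed event")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="efs_time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox partial-likelihood maximization failed to converge: {exc}"
        ) from exc
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "HR": summary["exp(coef)"],
            "se": summary["se(coef)"],
            "z": summary["z"],
            "p": summary["p"],
        }
    )
    lrt = cph.log_likelihood_ratio_test()
    return CoxFit(
        table=table,
        lrt_statistic=float(lrt.test_statistic),
        lrt_df=int(lrt.degrees_freedom),
        lrt_p=float(lrt.p_value),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def km_logrank_by_burden(
    clinical: Sequence[ClinicalRecord],
    burdens: Mapping[str, int],
    threshold: int = 100,
) -> dict:
    """Kaplan-Meier curves and log-rank test for high vs low burden.

    High group: burden strictly greater than the threshold; low group:
    burden <= threshold (the boundary value goes low).  Returns the two
    product-limit curves, the chi-square statistic (df 1) and its p-value.
    """
    missing = [r.patient_id for r in clinical if r.patient_id not in burdens]
    if missing:
        raise ValueError(f"patients without a burden value: {missing}")
    high = [r for r in clinical if burdens[r.patient_id] > threshold]
    low = [r for r in clinical if burdens[r.patient_id] <= threshold]
    if not high or not low:
        raise ValueError(
            f"burden threshold {threshold} leaves an empty group "
            f"(high={len(high)}, low={len(low)}); choose a different threshold"
        )
    curves = {}
    for name, group in (("high", high), ("low", low)):
        km = KaplanMeierFitter()
        km.fit(
            [r.efs_time for r in group],
            [r.event for r in group],
            label=name,
        )
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[name] = curve
    res = logrank_test(
        [r.efs_time for r in high],
        [r.efs_time for r in low],
        event_observed_A=[r.event for r in high],
        event_observed_B=[r.event for r in low],
    )
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
        "n_high": len(high),
        "n_low": len(low),
    }
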