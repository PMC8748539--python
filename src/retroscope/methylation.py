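"""TE-promoter methylation: probe mapping and group comparison.

450K-style array probes are mapped to ±500-bp windows around the
transcription start of Alu elements and full-length LINE-1 (only
near-intact, ~6 kb LINE-1 can be autonomously active, so truncated
copies are excluded).  Probe M-values (log2 beta odds) are averaged per
TE subfamily per sample, subfamilies are grouped by evolutionary age
(young elements being the transcriptionally competent ones), and groups
are compared with the unpaired two-sample Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .model import (
    REGION_PRIORITY,
    ProbeRecord,
    RepeatElement,
    RepeatSet,
    TEFamily,
)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)), elementwise; beta must lie in (0, 1).

    Strictly increasing, and antisymmetric about beta = 0.5:
    M(1 - b) = -M(b).
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    out = np.log2(arr / (1 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    if np.isscalar(beta):
        return float(out)
    return out


def select_full_length_line1(
    repeats: RepeatSet, min_length_bp: int = 5900
) -> list[RepeatElement]:
    """LINE-1 elements long enough to be near-intact (default >= 5900 bp)."""
    return [
        el
        for el in repeats
        if el.family is TEFamily.LINE1 and el.length >= min_length_bp
    ]


@dataclass(frozen=True)
class TSSWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    subfamily: str
    family: TEFamily
    truncated: bool = False


def te_tss_windows(
    elements: Iterable[RepeatElement],
    flank_bp: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TSSWindow]:
    """±flank_bp windows around each element's most-5' end.

    For '+' elements the most-5' end is the start coordinate; for '-'
    elements it is the end.  Windows are clamped at contig bounds and
    flagged as truncated.
    """
    windows = []
    for el in elements:
        anchor = el.start if el.strand == "+" else el.end
        lo, hi = anchor - flank_bp, anchor + flank_bp
        truncated = False
        if lo < 0:
            lo, truncated = 0, True
        if chrom_sizes is not None and el.chrom in chrom_sizes:
            size = chrom_sizes[el.chrom]
            if hi > size:
                hi, truncated = size, True
        windows.append(
            TSSWindow(
                chrom=el.chrom,
                start=lo,
                end=hi,
                strand=el.strand,
                subfamily=el.subfamily,
                family=el.family,
                truncated=truncated,
            )
        )
    return windows


def map_probes_to_windows(
    probes: Sequence[ProbeRecord],
    alu_windows: Sequence[TSSWindow],
    line1_windows: Sequence[TSSWindow],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign probes to TE TSS windows; ambiguous probes are excluded.

    A probe inside windows of two or more distinct Alu subfamilies is
    excluded (``multi_subfamily``); a probe inside both an Alu and a
    LINE-1 window is excluded (``cross_family``); several windows of one
    subfamily collapse to a single assignment.  Returns
    ``(assignments, exclusions)``; together with the unassigned rest they
    partition the probe set.
    """
    trees: dict[str, IntervalTree] = {}
    for window in list(alu_windows) + list(line1_windows):
        if window.end > window.start:
            trees.setdefault(window.chrom, IntervalTree()).addi(
                window.start, window.end, (window.family.value, window.subfamily)
            )
    assigned, excluded = [], []
    for probe in probes:
        tree = trees.get(probe.chrom)
        memberships = set()
        if tree is not None:
            memberships = {iv.data for iv in tree[probe.pos - 1]}
        if not memberships:
            continue
        families = {fam for fam, _ in memberships}
        if len(families) > 1:
            excluded.append((probe.probe_id, "cross_family"))
            continue
        if len(memberships) > 1:
            excluded.append((probe.probe_id, "multi_subfamily"))
            continue
        family, subfamily = next(iter(memberships))
        assigned.append((probe.probe_id, family, subfamily))
    assignments = pd.DataFrame(
        assigned, columns=["probe_id", "family", "subfamily"]
    )
    exclusions = pd.DataFrame(excluded, columns=["probe_id", "reason"])
    return assignments, exclusions


def subfamily_sample_means(
    assignments: pd.DataFrame, m_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Mean M of each subfamily's assigned probes, per sample."""
    missing = sorted(set(assignments["probe_id"]) - set(m_matrix.index))
    if missing:
        raise ValueError(
            f"assigned probes missing from the M matrix: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    joined = m_matrix.loc[assignments["probe_id"]].copy()
    joined.index = pd.Index(assignments["subfamily"].to_numpy(), name="subfamily")
    means = joined.groupby(level="subfamily").mean()
    return means.sort_index()


def age_category(subfamily: str, family: TEFamily) -> str:
    """Evolutionary-age category of a LINE-1 or Alu subfamily.

    LINE-1: L1HS and the L1PA lineage are young, other L1P intermediate,
    L1M old.  Alu: AluY young, AluS intermediate, everything else
    (AluJ, FLAM/FRAM monomers) old.
    """
    if family is TEFamily.LINE1:
        if subfamily == "L1HS" or subfamily.startswith("L1PA"):
            return "young"
        if subfamily.startswith("L1P"):
            return "intermediate"
        if subfamily.startswith("L1M"):
            return "old"
        raise ValueError(f"LINE-1 subfamily {subfamily!r} has no age category")
    if family is TEFamily.ALU:
        if subfamily.startswith("AluY"):
            return "young"
        if subfamily.startswith("AluS"):
            return "intermediate"
        if subfamily.startswith(("Alu", "FLAM", "FRAM")):
            return "old"
        raise ValueError(f"Alu subfamily {subfamily!r} has no age category")
    raise ValueError(f"age categories are defined for LINE1 and ALU, not {family}")


def age_category_means(
    subfamily_means: pd.DataFrame, family: TEFamily
) -> pd.DataFrame:
    """Unweighted mean over subfamily means within each age category."""
    cats = pd.Index(
        [age_category(sub, family) for sub in subfamily_means.index], name="age"
    )
    grouped = subfamily_means.set_axis(cats).groupby(level="age").mean()
    order = [c for c in ("young", "intermediate", "old") if c in grouped.index]
    return grouped.loc[order]


def region_priority_label(region_annotations: Sequence[str]) -> str:
    """Pick the highest-priority region annotation for a probe.

    Priority: TSS1500 > TSS200 > 5UTR > FirstExon > Body > 3UTR.
    """
    if not region_annotations:
        raise ValueError("empty region annotation list")
    order = {region: i for i, region in enumerate(REGION_PRIORITY)}
    unknown = [r for r in region_annotations if r not in order]
    if unknown:
        raise ValueError(f"unknown region annotations: {unknown}")
    return min(region_annotations, key=order.__getitem__)


def group_compare_wilcoxon(values_a, values_b, alternative: str = "two-sided") -> dict:
    """Unpaired two-sample Wilcoxon rank-sum test.

    Exact null enumeration when both groups have n <= 8 and the pooled
    data carry no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns ``{"statistic": U, "p_value": p}``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # fully tied data: the test has no information; U is its null mean
        return {"statistic": a.size * b.size / 2.0, "p_value": 1.0}
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
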