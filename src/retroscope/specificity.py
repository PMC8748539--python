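"""Polymorphic filtering against a population insertion catalog.

Insertions segregating in the general population (e.g., the 1000 Genomes
phase-3 MEI release) are not disease-specific and are removed before the
germline/somatic analysis.  A call is considered polymorphic when ANY
same-family catalog entry on the same chromosome lies within
``distance_bp`` of it (pure filtering, no one-to-one consumption).
HERV-K calls always pass because the population catalog reports no
HERV-K insertions.

``scan_filter_distances`` reports the remaining-call count across a grid
of distances; the working threshold (default 20 bp) is a configuration
value chosen by inspecting that table, not auto-selected.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ConsensusInsertion, TEFamily

#: default distance grid for the threshold scan
DEFAULT_SCAN_GRID = tuple(range(0, 101, 5))


def _catalog_positions(catalog: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    by_key: dict[tuple[str, str], np.ndarray] = {}
    if catalog.empty:
        return by_key
    for (chrom, family), group in catalog.groupby(["chrom", "family"], sort=False):
        by_key[(chrom, family)] = np.sort(group["pos"].to_numpy())
    return by_key


def _min_catalog_distance(
    calls: Sequence[ConsensusInsertion], catalog: pd.DataFrame
) -> np.ndarray:
    """Distance from each call to its nearest same-family catalog entry.

    HERV-K calls and calls with no same-family entries on their chromosome
    get +inf (never filtered).
    """
    positions = _catalog_positions(catalog)
    dist = np.full(len(calls), np.inf)
    for i, call in enumerate(calls):
        if call.te_family is TEFamily.HERVK:
            continue
        entries = positions.get((call.chrom, call.te_family.value))
        if entries is None or len(entries) == 0:
            continue
        j = np.searchsorted(entries, call.final_pos)
        best = np.inf
        if j < len(entries):
            best = min(best, abs(int(entries[j]) - call.final_pos))
        if j > 0:
            best = min(best, abs(int(entries[j - 1]) - call.final_pos))
        dist[i] = best
    return dist


def scan_filter_distances(
    calls: Sequence[ConsensusInsertion],
    catalog: pd.DataFrame,
    distances: Sequence[int] = DEFAULT_SCAN_GRID,
) -> pd.DataFrame:
    """Count calls surviving the polymorphic filter at each distance.

    Returns a frame ``distance, remaining`` with counts non-increasing in
    distance; the table mirrors the threshold-selection scan used to pick
    the working cutoff.
    """
    distances = list(distances)
    if any(d < 0 for d in distances):
        raise ValueError("distances must be >= 0")
    if sorted(distances) != distances:
        raise ValueError("distances must be sorted ascending")
    dist = _min_catalog_distance(calls, catalog)
    remaining = [(d, int((dist > d).sum())) for d in distances]
    return pd.DataFrame(remaining, columns=["distance", "remaining"])


def filter_polymorphic(
    calls: Sequence[ConsensusInsertion],
    catalog: pd.DataFrame,
    distance_bp: int = 20,
) -> list[ConsensusInsertion]:
    """Return the patient-specific calls (nearest catalog entry > distance_bp)."""
    if distance_bp < 0:
        raise ValueError(f"distance_bp must be >= 0, got {distance_bp}")
    dist = _min_catalog_distance(calls, catalog)
    return [call for call, d in zip(calls, dist) if d > distance_bp]
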