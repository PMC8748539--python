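"""Two-caller consensus: reconcile precise and imprecise call sets.

Calls from the two callers are considered to describe the same insertion
when they share chromosome and TE family and lie within
``consensus_window_bp`` (inclusive) of each other.  Matching is
one-to-one greedy nearest-first: candidate pairs are ordered by |Δpos|
ascending (ties broken by smaller primary position, then smaller
secondary position) and accepted while both calls remain unconsumed.
The primary caller's coordinate becomes the consensus position, because
that caller resolves insertion breakpoints precisely while the secondary
caller reports a confidence interval.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .model import Caller, ConsensusInsertion, TECall

logger = logging.getLogger(__name__)


def greedy_nearest_pairs(
    a_items: list[tuple[int, object]],
    b_items: list[tuple[int, object]],
    window_bp: int,
) -> tuple[list[tuple[object, object]], list[object], list[object]]:
    """One-to-one greedy nearest-first pairing of two position-keyed lists.

    ``a_items``/``b_items`` are ``(pos, payload)`` tuples assumed already
    restricted to one (chromosome, family) stratum.  Returns
    ``(pairs, unmatched_a, unmatched_b)``.  Shared by consensus matching
    and tumor/normal classification, which use identical semantics.
    """
    candidates = []
    for i, (pa, _) in enumerate(a_items):
        for j, (pb, _) in enumerate(b_items):
            d = abs(pa - pb)
            if d <= window_bp:
                candidates.append((d, pa, pb, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a_items[i][1], b_items[j][1]))
    unmatched_a = [x for k, (_, x) in enumerate(a_items) if k not in used_a]
    unmatched_b = [x for k, (_, x) in enumerate(b_items) if k not in used_b]
    return pairs, unmatched_a, unmatched_b


def match_consensus(
    primary_calls: list[TECall],
    secondary_calls: list[TECall],
    window_bp: int = 100,
) -> tuple[list[ConsensusInsertion], list[TECall], list[TECall]]:
    """Reconcile one sample's two call sets into consensus insertions.

    Returns ``(consensus, unmatched_primary, unmatched_secondary)``;
    unmatched calls are excluded from all downstream analyses.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    samples = {c.sample_id for c in primary_calls} | {
        c.sample_id for c in secondary_calls
    }
    if len(samples) > 1:
        raise ValueError(f"calls from mixed samples: {sorted(samples)}")
    for c in primary_calls:
        if c.caller is not Caller.PRIMARY:
            raise ValueError("primary_calls contains a non-primary call")
    for c in secondary_calls:
        if c.caller is not Caller.SECONDARY:
            raise ValueError("secondary_calls contains a non-secondary call")

    strata: dict[tuple[str, str], tuple[list, list]] = defaultdict(
        lambda: ([], [])
    )
    for c in primary_calls:
        strata[(c.chrom, c.te_family.value)][0].append((c.pos, c))
    for c in secondary_calls:
        strata[(c.chrom, c.te_family.value)][1].append((c.pos, c))

    consensus: list[ConsensusInsertion] = []
    unmatched_p: list[TECall] = []
    unmatched_s: list[TECall] = []
    for key in sorted(strata):
        a_items, b_items = strata[key]
        a_items.sort(key=lambda t: t[0])
        b_items.sort(key=lambda t: t[0])
        pairs, rest_a, rest_b = greedy_nearest_pairs(a_items, b_items, window_bp)
        for p, s in pairs:
            subfamily = p.subfamily if p.subfamily is not None else s.subfamily
            if (
                p.subfamily is not None
                and s.subfamily is not None
                and p.subfamily != s.subfamily
            ):
                logger.info(
                    "subfamily disagreement at %s:%d (%s vs %s); keeping the "
                    "primary caller's %s",
                    p.chrom,
                    p.pos,
                    p.subfamily,
                    s.subfamily,
                    p.subfamily,
                )
            consensus.append(
                ConsensusInsertion(
                    patient_id=p.patient_id,
                    sample_id=p.sample_id,
                    tissue=p.tissue,
                    chrom=p.chrom,
                    final_pos=p.pos,
                    te_family=p.te_family,
                    subfamily=subfamily,
                    tsd_sequence=p.tsd_sequence,
                    primary_pos=p.pos,
                    secondary_pos=s.pos,
                )
            )
        unmatched_p.extend(rest_a)
        unmatched_s.extend(rest_b)
    consensus.sort(key=lambda c: (c.chrom, c.final_pos, c.te_family.value))
    return consensus, unmatched_p, unmatched_s
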