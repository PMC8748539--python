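"""Germline/somatic classification of patient-specific insertions.

Within one patient, a tumor call matched by a same-chromosome,
same-family normal call inside ``somatic_window_bp`` (default 100 bp,
inclusive) is germline — the insertion was inherited and is present in
both tissues.  The matched pair is reported once, at the tumor call's
coordinate.  Unmatched tumor calls are tumor-specific somatic events;
unmatched normal calls are normal-specific somatic events.  Matching is
one-to-one greedy nearest-first with the same tie rules as two-caller
consensus.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import pandas as pd

from .consensus import greedy_nearest_pairs
from .model import ClassifiedInsertion, ConsensusInsertion, PatientClass, Tissue


def classify_patient(
    tumor_calls: Sequence[ConsensusInsertion],
    normal_calls: Sequence[ConsensusInsertion],
    window_bp: int = 100,
) -> list[ClassifiedInsertion]:
    """Classify one patient's patient-specific calls by tumor/normal pairing."""
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    patients = {c.patient_id for c in tumor_calls} | {
        c.patient_id for c in normal_calls
    }
    if len(patients) > 1:
        raise ValueError(f"calls from mixed patients: {sorted(patients)}")
    for c in tumor_calls:
        if c.tissue is not Tissue.TUMOR:
            raise ValueError("tumor_calls contains a non-tumor call")
    for c in normal_calls:
        if c.tissue is not Tissue.NORMAL:
            raise ValueError("normal_calls contains a non-normal call")

    strata: dict[tuple[str, str], tuple[list, list]] = defaultdict(lambda: ([], []))
    for c in tumor_calls:
        strata[(c.chrom, c.te_family.value)][0].append((c.final_pos, c))
    for c in normal_calls:
        strata[(c.chrom, c.te_family.value)][1].append((c.final_pos, c))

    out: list[ClassifiedInsertion] = []
    for key in sorted(strata):
        t_items, n_items = strata[key]
        t_items.sort(key=lambda x: x[0])
        n_items.sort(key=lambda x: x[0])
        pairs, rest_t, rest_n = greedy_nearest_pairs(t_items, n_items, window_bp)
        for t, n in pairs:
            out.append(
                ClassifiedInsertion(
                    patient_id=t.patient_id,
                    chrom=t.chrom,
                    final_pos=t.final_pos,
                    te_family=t.te_family,
                    subfamily=t.subfamily,
                    tsd_sequence=t.tsd_sequence,
                    patient_class=PatientClass.GERMLINE,
                    partner_pos=n.final_pos,
                )
            )
        for t in rest_t:
            out.append(
                ClassifiedInsertion(
                    patient_id=t.patient_id,
                    chrom=t.chrom,
                    final_pos=t.final_pos,
                    te_family=t.te_family,
                    subfamily=t.subfamily,
                    tsd_sequence=t.tsd_sequence,
                    patient_class=PatientClass.TUMOR_SOMATIC,
                )
            )
        for n in rest_n:
            out.append(
                ClassifiedInsertion(
                    patient_id=n.patient_id,
                    chrom=n.chrom,
                    final_pos=n.final_pos,
                    te_family=n.te_family,
                    subfamily=n.subfamily,
                    tsd_sequence=n.tsd_sequence,
                    patient_class=PatientClass.NORMAL_SOMATIC,
                )
            )
    out.sort(key=lambda c: (c.chrom, c.final_pos, c.patient_class.value))
    return out


def summarize_classification(
    cohort: Sequence[ClassifiedInsertion],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient and cohort classification totals.

    Returns ``(per_patient, totals)``.  ``per_patient`` has one row per
    patient sorted by id with germline / tumor_somatic / normal_somatic /
    total counts.  ``totals`` is a one-row cohort summary that also
    reports how many patients carry at least one tumor-specific somatic
    insertion and the per-patient min/max of that count, plus raw-call
    conservation (each germline record merges a tumor and a normal call).
    """
    classes = [pc.value for pc in PatientClass]
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {c: 0 for c in classes})
    for ins in cohort:
        counts[ins.patient_id][ins.patient_class.value] += 1
    rows = []
    for pid in sorted(counts):
        row = {"patient_id": pid, **counts[pid]}
        row["total"] = sum(counts[pid][c] for c in classes)
        rows.append(row)
    per_patient = pd.DataFrame(
        rows, columns=["patient_id", *classes, "total"]
    )
    if per_patient.empty:
        per_patient = pd.DataFrame(columns=["patient_id", *classes, "total"])
        totals = {c: 0 for c in classes}
        totals.update(
            total=0,
            n_patients=0,
            patients_with_tumor_somatic=0,
            tumor_somatic_min=0,
            tumor_somatic_max=0,
            raw_calls=0,
        )
        return per_patient, pd.DataFrame([totals])
    totals = {c: int(per_patient[c].sum()) for c in classes}
    totals["total"] = int(per_patient["total"].sum())
    totals["n_patients"] = len(per_patient)
    ts = per_patient["tumor_somatic"]
    totals["patients_with_tumor_somatic"] = int((ts > 0).sum())
    carriers = ts[ts > 0]
    # per-patient range among patients that carry any tumor-somatic insertion
    totals["tumor_somatic_min"] = int(carriers.min()) if len(carriers) else 0
    totals["tumor_somatic_max"] = int(carriers.max()) if len(carriers) else 0
    # germline records each absorb two raw calls (tumor + normal)
    totals["raw_calls"] = totals["total"] + totals["germline"]
    return per_patient, pd.DataFrame([totals])
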