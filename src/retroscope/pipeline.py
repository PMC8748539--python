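"""End-to-end orchestration: consensus → specificity → classification →
features → methylation → association.

``run_all`` consumes a directory laid out like the output of
:func:`retroscope.simulate.generate_cohort` (or equivalently prepared
real inputs) and writes every report table as TSV plus a manifest with
input checksums, the resolved configuration and the seed, so that a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .classify import classify_patient, summarize_classification
from .config import PipelineConfig
from .consensus import match_consensus
from .features import (
    assign_genomic_context,
    cfs_overlap_summary,
    context_summary,
    exon_proximity,
    flanking_composition,
    gene_length_strata,
    gene_list_intersection,
    gene_patient_table,
    recurrent_gene_report,
    tsd_length_histogram,
)
from .methylation import (
    age_category_means,
    beta_to_m,
    group_compare_wilcoxon,
    map_probes_to_windows,
    select_full_length_line1,
    subfamily_sample_means,
    te_tss_windows,
)
from .model import Caller, PatientClass, TEFamily, Tissue
from .specificity import DEFAULT_SCAN_GRID, filter_polymorphic, scan_filter_distances
from .survival import (
    dummy_encode,
    fit_cox_efs,
    km_logrank_by_burden,
    spearman_matrix,
    standardize_features,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _discover_patients(calls_dir: Path) -> list[str]:
    pids = sorted(
        {p.name.split("_")[0] for p in calls_dir.glob("*_tumor_primary_caller.vcf")}
    )
    if not pids:
        raise StageError("consensus", f"no caller VCFs found under {calls_dir}")
    return pids


def run_all(
    bundle_dir,
    out_dir,
    config: PipelineConfig | None = None,
    gene_list_path=None,
) -> dict:
    """Run the full pipeline on an input bundle; returns the result tables."""
    config = config or PipelineConfig()
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    results: dict = {"config": config.to_dict()}

    required = [
        "genome.fa",
        "genes.gff3",
        "repeats.tsv",
        "cfs.bed",
        "catalog.bed",
        "beta.csv",
        "manifest.csv",
        "sample_groups.csv",
        "clinical.csv",
        "expression.csv",
    ]
    for name in required:
        if not (bundle / name).exists():
            raise StageError("inputs", f"missing input file {bundle / name}")

    # ---- consensus ------------------------------------------------------
    calls_dir = bundle / "calls"
    pids = _discover_patients(calls_dir)
    consensus_by_sample: dict[tuple[str, Tissue], list] = {}
    n_primary = n_secondary = 0
    for pid in pids:
        for tissue in (Tissue.TUMOR, Tissue.NORMAL):
            prim_path = calls_dir / f"{pid}_{tissue.value}_primary_caller.vcf"
            sec_path = calls_dir / f"{pid}_{tissue.value}_secondary_caller.vcf"
            try:
                primary = rio.read_mei_calls(prim_path, Caller.PRIMARY, pid, tissue)
                secondary = rio.read_mei_calls(sec_path, Caller.SECONDARY, pid, tissue)
            except (OSError, rio.FormatError) as exc:
                raise StageError("consensus", str(exc)) from exc
            n_primary += len(primary)
            n_secondary += len(secondary)
            cons, _, _ = match_consensus(
                primary, secondary, config.consensus_window_bp
            )
            consensus_by_sample[(pid, tissue)] = cons
    all_consensus = [c for calls in consensus_by_sample.values() for c in calls]
    logger.info(
        "consensus: %d primary + %d secondary calls -> %d consensus",
        n_primary,
        n_secondary,
        len(all_consensus),
    )
    tables["consensus_calls"] = rio.consensus_to_frame(all_consensus)

    # ---- specificity -----------------------------------------------------
    try:
        catalog = rio.read_catalog(bundle / "catalog.bed")
    except rio.FormatError as exc:
        raise StageError("specificity", str(exc)) from exc
    scan = scan_filter_distances(all_consensus, catalog, DEFAULT_SCAN_GRID)
    tables["polymorphic_scan"] = scan
    specific_by_sample = {
        key: filter_polymorphic(calls, catalog, config.polymorphic_distance_bp)
        for key, calls in consensus_by_sample.items()
    }
    n_specific = sum(len(v) for v in specific_by_sample.values())
    logger.info(
        "specificity: %d consensus -> %d patient-specific at %d bp",
        len(all_consensus),
        n_specific,
        config.polymorphic_distance_bp,
    )

    # ---- classification --------------------------------------------------
    classified = []
    for pid in pids:
        classified.extend(
            classify_patient(
                specific_by_sample[(pid, Tissue.TUMOR)],
                specific_by_sample[(pid, Tissue.NORMAL)],
                config.somatic_window_bp,
            )
        )
    per_patient, totals = summarize_classification(classified)
    tables["classification_per_patient"] = per_patient
    tables["classification_totals"] = totals
    tables["classified_insertions"] = rio.classified_to_frame(classified)
    logger.info(
        "classification: %d records (%d germline, %d tumor-somatic, %d normal-somatic)",
        len(classified),
        int(totals["germline"].iloc[0]),
        int(totals["tumor_somatic"].iloc[0]),
        int(totals["normal_somatic"].iloc[0]),
    )

    # ---- insertion features ---------------------------------------------
    try:
        genes = rio.read_gene_models(bundle / "genes.gff3")
        cfs = rio.read_intervals(bundle / "cfs.bed")
    except rio.FormatError as exc:
        raise StageError("features", str(exc)) from exc
    hist, tsd_mode, n_no_tsd = tsd_length_histogram(classified)
    tables["tsd_histogram"] = hist.rename_axis("tsd_length").reset_index()
    results["tsd_mode"] = tsd_mode
    results["n_calls_without_tsd"] = n_no_tsd

    fractions, n_used, n_excl = flanking_composition(
        bundle / "genome.fa", classified, config.flank_bp
    )
    tables["flanking_composition"] = fractions.reset_index()
    results["flanking_sites_used"] = n_used
    results["flanking_sites_excluded"] = n_excl

    labels = assign_genomic_context(classified, genes)
    ctx = context_summary(labels, by_family=True)
    tables["genomic_context"] = ctx
    results["n_overlapping_genes"] = ctx.attrs["n_overlapping"]

    strata = gene_length_strata(genes, labels)
    tables["gene_length_strata"] = pd.DataFrame(
        [
            {
                "n_genes": strata["n_genes"],
                "n_inserted": strata["n_inserted"],
                "inserted_fraction_pct": strata["inserted_fraction_pct"],
                "median_inserted": strata["median_inserted"],
                "median_non_inserted": strata["median_non_inserted"],
            }
        ]
    )
    if strata["n_inserted"] and len(strata["non_inserted_lengths"]):
        strata_test = group_compare_wilcoxon(
            strata["inserted_lengths"], strata["non_inserted_lengths"]
        )
        results["gene_length_wilcoxon_p"] = strata_test["p_value"]

    cfs_summary = cfs_overlap_summary(classified, cfs)
    tables["cfs_overlap"] = pd.DataFrame([cfs_summary])
    results["cfs"] = cfs_summary

    tables["affected_genes"] = gene_patient_table(classified, genes)
    tables["recurrent_genes"] = recurrent_gene_report(
        classified, genes, config.recurrence_min_patients
    )
    if gene_list_path is not None:
        symbols = [
            line.strip()
            for line in Path(gene_list_path).read_text().splitlines()
            if line.strip()
        ]
        tables["cancer_gene_intersection"] = gene_list_intersection(
            tables["affected_genes"], symbols
        )
    tables["exon_proximity"] = exon_proximity(labels, genes, config.somatic_window_bp)
    logger.info("features: %d context labels, %d recurrent genes",
                len(labels), len(tables["recurrent_genes"]))

    # ---- methylation -----------------------------------------------------
    try:
        beta, probes = rio.read_beta_and_manifest(
            bundle / "beta.csv", bundle / "manifest.csv"
        )
        repeats = rio.read_repeats(bundle / "repeats.tsv")
    except rio.FormatError as exc:
        raise StageError("methylation", str(exc)) from exc
    groups = pd.read_csv(bundle / "sample_groups.csv", dtype=str)
    line1 = select_full_length_line1(repeats, config.full_length_line1_min_bp)
    alu = [el for el in repeats if el.family is TEFamily.ALU]
    l1_windows = te_tss_windows(line1, config.tss_flank_bp)
    alu_windows = te_tss_windows(alu, config.tss_flank_bp)
    assignments, exclusions = map_probes_to_windows(probes, alu_windows, l1_windows)
    tables["probe_assignments"] = assignments
    tables["probe_exclusions"] = exclusions
    m_matrix = beta_to_m(beta)
    sub_means = subfamily_sample_means(assignments, m_matrix)
    tables["subfamily_sample_means"] = sub_means.reset_index()

    tumor_samples = groups.loc[groups["group"] == "tumor", "sample_id"].tolist()
    control_samples = groups.loc[groups["group"] == "control", "sample_id"].tolist()
    meth_rows = []
    age_means_by_family = {}
    for family in (TEFamily.LINE1, TEFamily.ALU):
        fam_subs = assignments.loc[
            assignments["family"] == family.value, "subfamily"
        ].unique()
        fam_means = sub_means.loc[[s for s in sub_means.index if s in set(fam_subs)]]
        if fam_means.empty:
            continue
        ages = age_category_means(fam_means, family)
        age_means_by_family[family.value] = ages
        for age in ages.index:
            t_vals = ages.loc[age, [s for s in tumor_samples if s in ages.columns]]
            c_vals = ages.loc[age, [s for s in control_samples if s in ages.columns]]
            if len(t_vals) == 0 or len(c_vals) == 0:
                continue
            test = group_compare_wilcoxon(t_vals, c_vals)
            meth_rows.append(
                {
                    "family": family.value,
                    "age": age,
                    "tumor_mean_m": float(np.mean(t_vals)),
                    "control_mean_m": float(np.mean(c_vals)),
                    "statistic": test["statistic"],
                    "p_value": test["p_value"],
                }
            )
    tables["methylation_age_comparison"] = pd.DataFrame(meth_rows)
    logger.info(
        "methylation: %d probes assigned, %d excluded",
        len(assignments),
        len(exclusions),
    )

    # ---- association -----------------------------------------------------
    try:
        clinical = rio.read_clinical(bundle / "clinical.csv")
    except rio.FormatError as exc:
        raise StageError("association", str(exc)) from exc
    expression = pd.read_csv(bundle / "expression.csv", index_col="patient_id")
    burdens = {
        pid: sum(
            1
            for c in classified
            if c.patient_id == pid
            and c.patient_class in (PatientClass.GERMLINE, PatientClass.TUMOR_SOMATIC)
        )
        for pid in pids
    }
    tables["burdens"] = pd.DataFrame(
        sorted(burdens.items()), columns=["patient_id", "burden"]
    )

    activity = expression.copy()
    for family, ages in age_means_by_family.items():
        for age in ages.index:
            cols = [s for s in ages.columns if s in activity.index]
            activity[f"meth_{family}_{age}"] = ages.loc[age, cols].reindex(
                activity.index
            )
    activity["insertion_burden"] = pd.Series(burdens).reindex(activity.index)

    te_std = standardize_features(activity)
    rho, pmat, sig = spearman_matrix(te_std, config.alpha)
    tables["spearman_rho"] = rho.reset_index(names="feature")
    tables["spearman_p"] = pmat.reset_index(names="feature")

    clin_df = pd.DataFrame(
        {
            "age_dx": [r.age_dx for r in clinical],
            "disease_status_dx": [r.disease_status_dx for r in clinical],
            "primary_site": [r.primary_site for r in clinical],
        },
        index=pd.Index([r.patient_id for r in clinical], name="patient_id"),
    )
    covariates = pd.concat(
        [
            te_std,
            standardize_features(clin_df[["age_dx"]]),
            dummy_encode(clin_df["disease_status_dx"], "status"),
            dummy_encode(clin_df["primary_site"], "site"),
        ],
        axis=1,
        join="inner",
    )
    try:
        cox = fit_cox_efs(covariates, clinical)
    except (RuntimeError, ValueError) as exc:
        raise StageError("association", f"Cox fit failed: {exc}") from exc
    cox_table = cox.table.reset_index(names="feature")
    tables["cox_model"] = cox_table
    results["cox"] = {
        "lrt_statistic": cox.lrt_statistic,
        "lrt_df": cox.lrt_df,
        "lrt_p": cox.lrt_p,
        "n": cox.n,
        "n_events": cox.n_events,
    }
    try:
        km = km_logrank_by_burden(clinical, burdens, config.burden_threshold)
    except ValueError as exc:
        raise StageError("association", str(exc)) from exc
    tables["km_high"] = km["curves"]["high"]
    tables["km_low"] = km["curves"]["low"]
    tables["logrank"] = pd.DataFrame(
        [
            {
                "statistic": km["statistic"],
                "p_value": km["p_value"],
                "n_high": km["n_high"],
                "n_low": km["n_low"],
            }
        ]
    )
    results["logrank_p"] = km["p_value"]
    logger.info("association: Cox LRT %.2f on %d df", cox.lrt_statistic, cox.lrt_df)

    # ---- reports ---------------------------------------------------------
    rio.write_report(tables, out)
    manifest = {
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(bundle / name) for name in required if (bundle / name).exists()
        },
        "n_consensus": len(all_consensus),
        "n_patient_specific": n_specific,
    }
    manifest["inputs"].update(
        {f"calls/{p.name}": _sha256(p) for p in sorted(calls_dir.glob("*.vcf"))}
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["tables"] = tables
    return results
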