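import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from retroscope.model import Caller, Tissue
from retroscope.simulate import (
    SimParams,
    _rng,
    emit_caller_calls,
    generate_cohort,
    simulate_clinical,
    simulate_genes,
    simulate_insertion_truth,
)

SMALL = dict(
    n_patients=4,
    germline_rate=20.0,
    tumor_somatic_rate=2.0,
    n_polymorphic_sites=30,
    genes_per_chrom=30,
    chrom_length=300_000,
)


def bundle_digest(path):
    h = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundle(self, tmp_path):
        params = SimParams(**SMALL)
        generate_cohort(params, 7, tmp_path / "a")
        generate_cohort(params, 7, tmp_path / "b")
        assert bundle_digest(tmp_path / "a") == bundle_digest(tmp_path / "b")

    def test_different_seed_moves_sites(self, tmp_path):
        params = SimParams(**SMALL)
        t1 = generate_cohort(params, 7, tmp_path / "a")
        t2 = generate_cohort(params, 8, tmp_path / "b")
        assert set(zip(t1.insertions.chrom, t1.insertions.pos)) != set(
            zip(t2.insertions.chrom, t2.insertions.pos)
        )


class TestCallerEmission:
    def _truth(self, seed=3):
        params = SimParams(**SMALL)
        genes = simulate_genes(params, seed)
        truth, _ = simulate_insertion_truth(params, genes, seed)
        return params, truth

    def test_noiseless_limit_both_callers_exact(self):
        params, truth = self._truth()
        params = SimParams(**{**SMALL,
            "fn_rate_primary": 0.0, "fn_rate_secondary": 0.0,
            "fp_rate_primary": 0.0, "fp_rate_secondary": 0.0,
            "caller_jitter_bp": 0})
        prim = emit_caller_calls(truth, "P001", Tissue.TUMOR, Caller.PRIMARY, params, _rng(0, "p"))
        sec = emit_caller_calls(truth, "P001", Tissue.TUMOR, Caller.SECONDARY, params, _rng(0, "s"))
        assert [(c.chrom, c.pos) for c in prim] == [(c.chrom, c.pos) for c in sec]
        expected = truth.query(
            "patient_id == 'P001' and true_class != 'normal_somatic'"
        )
        assert {(c.chrom, c.pos) for c in prim} == set(zip(expected.chrom, expected.pos))

    def test_total_fn_gives_empty_call_set(self):
        params, truth = self._truth()
        params = SimParams(**{**SMALL, "fn_rate_primary": 1.0, "fp_rate_primary": 0.0})
        calls = emit_caller_calls(truth, "P001", Tissue.TUMOR, Caller.PRIMARY, params, _rng(0, "x"))
        assert calls == []

    def test_fp_count_matches_binomial_oracle(self):
        """Observed false-positive counts across seeds stay within 3 SD of
        the Binomial(N, r) mean computed analytically."""
        params, truth = self._truth()
        r = 0.1
        params = SimParams(**{**SMALL, "fn_rate_primary": 0.0, "fp_rate_primary": r})
        n_true = len(
            truth.query("patient_id == 'P001' and true_class != 'normal_somatic'")
        )
        counts = []
        for seed in range(50):
            calls = emit_caller_calls(
                truth, "P001", Tissue.TUMOR, Caller.PRIMARY, params, _rng(seed, "fp")
            )
            counts.append(len(calls) - n_true)
        mean = np.mean(counts)
        se = np.sqrt(n_true * r * (1 - r) / 50)
        assert abs(mean - n_true * r) < 3 * se

    def test_secondary_ci_contains_position(self):
        params, truth = self._truth()
        calls = emit_caller_calls(
            truth, "P001", Tissue.NORMAL, Caller.SECONDARY, params, _rng(1, "ci")
        )
        assert calls
        assert all(c.ci_lo <= c.pos <= c.ci_hi for c in calls)


class TestMarginalCounts:
    def test_germline_counts_within_poisson_band_over_seeds(self):
        """Mean planted germline count over 20 seeds stays within 3 SD of
        the configured rate (overdispersion disabled)."""
        params = SimParams(**{**SMALL, "burden_dispersion_shape": 0.0})
        rate, n_pat, n_seeds = params.germline_rate, params.n_patients, 20
        totals = []
        for seed in range(n_seeds):
            genes = simulate_genes(params, seed)
            truth, _ = simulate_insertion_truth(params, genes, seed)
            totals.append((truth.true_class == "germline").sum())
        mean_per_patient = np.mean(totals) / n_pat
        se = np.sqrt(rate / (n_pat * n_seeds))
        assert abs(mean_per_patient - rate) < 3 * se


class TestClinicalSimulation:
    def test_full_censoring(self):
        params = SimParams(censoring_rate=1.0)
        recs = simulate_clinical({"P1": 10, "P2": 200}, params, _rng(0, "c"))
        assert all(r.event == 0 for r in recs)

    def test_invalid_baseline_hazard(self):
        params = SimParams()
        object.__setattr__(params, "baseline_hazard", 0.0)
        with pytest.raises(ValueError, match="hazard"):
            simulate_clinical({"P1": 10}, params, _rng(0, "c"))

    def test_null_effect_logrank_type_one_error(self):
        """Under a null burden effect the log-rank test rejects at close
        to its nominal 5% rate (binomial 3 SD band over 200 seeds)."""
        from retroscope.survival import km_logrank_by_burden

        params = SimParams(burden_log_hazard=0.0, censoring_rate=0.2)
        n_seeds, rejections = 200, 0
        for seed in range(n_seeds):
            rng = _rng(seed, "null")
            burdens = {f"P{i:03d}": int(b) for i, b in enumerate(rng.gamma(4, 30, 40))}
            clinical = simulate_clinical(burdens, params, rng)
            try:
                out = km_logrank_by_burden(clinical, burdens, 100)
            except ValueError:
                continue  # a degenerate split; no test performed
            rejections += out["p_value"] < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds < 0.05 + band

    def test_strong_protective_effect_detected(self):
        """A strongly protective burden effect (log-hazard -1) at n=200 is
        detected by the log-rank test in the vast majority of seeds."""
        from retroscope.survival import km_logrank_by_burden

        params = SimParams(burden_log_hazard=-1.0, censoring_rate=0.2)
        hits, n_seeds = 0, 25
        for seed in range(n_seeds):
            rng = _rng(seed, "power")
            burdens = {f"P{i:03d}": int(b) for i, b in enumerate(rng.gamma(4, 30, 200))}
            clinical = simulate_clinical(burdens, params, rng)
            out = km_logrank_by_burden(clinical, burdens, 100)
            hits += out["p_value"] < 0.05
        assert hits >= 0.8 * n_seeds


class TestCapacity:
    def test_overfull_genome_rejected(self):
        params = SimParams(
            n_patients=2,
            germline_rate=500.0,
            chrom_length=20_000,
            n_chroms=1,
            genes_per_chrom=5,
            n_polymorphic_sites=5,
        )
        genes = simulate_genes(params, 0)
        with pytest.raises(ValueError, match="capacity"):
            simulate_insertion_truth(params, genes, 0)


class TestTruthLedgerShape:
    def test_every_emitted_call_traces_to_truth_or_fp(self, noiseless_bundle):
        bundle, truth = noiseless_bundle
        from retroscope import io as rio

        calls = rio.read_mei_calls(
            bundle / "calls" / "P001_tumor_primary_caller.vcf",
            Caller.PRIMARY, "P001", Tissue.TUMOR,
        )
        planted = set(
            zip(
                truth.insertions.query("patient_id == 'P001'").chrom,
                truth.insertions.query("patient_id == 'P001'").pos,
            )
        )
        assert all((c.chrom, c.pos) in planted for c in calls)

    def test_burden_equals_specific_tumor_truth(self, noiseless_bundle):
        _, truth = noiseless_bundle
        spec = truth.insertions.query("true_class in ('germline', 'tumor_somatic')")
        counted = spec.groupby("patient_id").size()
        for row in truth.patients.itertuples(index=False):
            assert counted.get(row.patient_id, 0) == row.true_burden
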