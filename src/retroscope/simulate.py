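"""Synthetic tumor/normal MEI cohort with a machine-readable truth ledger.

Generates every input the pipeline consumes — genome FASTA, gene models,
repeat annotation, common-fragile-site intervals, a polymorphic-insertion
catalog, per-sample two-caller call sets, methylation beta matrices, a
clinical table — with planted ground truth so that each downstream stage
can be tested for exact or statistical recovery.

What is planted, and where it surfaces downstream:

* germline / tumor-somatic / normal-somatic / polymorphic status per
  insertion (recovered by consensus + filtering + classification);
* TSD lengths drawn from a Binomial(30, mode/30) distribution, mode 15 bp
  (recovered by the TSD histogram);
* an A/T excess within ±10 bp of insertion sites over a 50% GC background
  (recovered by flanking composition);
* length-biased intronic gene targeting (recovered by the gene-length
  stratification);
* tumor hypomethylation of young-LINE-1 (and, milder, Alu) TSS probes
  (recovered by the methylation group comparison);
* a negative log-hazard of standardized insertion burden on event-free
  survival (recovered by the Cox fit and the burden-stratified
  Kaplan-Meier curves).

All randomness flows from one seed; named substreams keep the bundle
byte-identical across runs regardless of call order.
"""

from __future__ import annotations

import bisect
import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .model import (
    Caller,
    ClinicalRecord,
    Gene,
    GeneSet,
    ProbeRecord,
    RepeatElement,
    RepeatSet,
    TECall,
    TEFamily,
    Tissue,
    Transcript,
)

SUBFAMILIES = {
    TEFamily.LINE1: ["L1HS", "L1PA2", "L1PA3"],
    TEFamily.ALU: ["AluYa5", "AluYb8", "AluSx", "AluJb"],
    TEFamily.SVA: ["SVA_D", "SVA_E", "SVA_F"],
    TEFamily.HERVK: ["HERVK"],
}

#: subfamilies of planted methylation-bearing repeat elements, by family
METH_SUBFAMILIES = {
    TEFamily.LINE1: ["L1HS", "L1PA2", "L1PB1", "L1M5"],
    TEFamily.ALU: ["AluYa5", "AluYb8", "AluSx", "AluSp", "AluJb"],
}


@dataclass
class SimParams:
    """Study conditions of the synthetic cohort (defaults are the
    conditions every recovery test runs under)."""

    n_patients: int = 39
    n_chroms: int = 2
    chrom_length: int = 600_000
    gc_content: float = 0.5

    # per-patient mean insertion counts by class
    germline_rate: float = 80.0
    #: gamma shape of the per-patient germline rate mixture; smaller means
    #: more burden heterogeneity across patients (cohorts show a long
    #: right tail with a minority of patients above ~100 insertions)
    burden_dispersion_shape: float = 4.0
    tumor_somatic_rate: float = 4.0
    normal_somatic_rate: float = 0.2
    n_polymorphic_sites: int = 200
    polymorphic_carrier_prob: float = 0.3
    catalog_jitter_bp: int = 5

    family_weights: dict = field(
        default_factory=lambda: {"LINE1": 0.13, "ALU": 0.80, "SVA": 0.06, "HERVK": 0.01}
    )

    tsd_mode: int = 15
    tsd_max: int = 30
    #: Laplace scale of the discretized TSD length distribution; small
    #: values concentrate mass at the mode
    tsd_scale: float = 2.0
    at_enrichment: float = 0.15
    at_flank_bp: int = 10
    gene_length_bias_exponent: float = 1.0
    p_genic: float = 0.5
    genes_per_chrom: int = 100
    min_site_separation_bp: int = 300

    # caller noise profile
    caller_jitter_bp: int = 30
    consensus_window_bp: int = 100  # used only to validate the jitter
    fn_rate_primary: float = 0.01
    fn_rate_secondary: float = 0.01
    fp_rate_primary: float = 0.01
    fp_rate_secondary: float = 0.01

    # methylation
    n_control_samples: int = 3
    probes_per_subfamily: int = 20
    m_base: float = 2.0
    m_shift_young_line1: float = -0.5
    m_shift_alu: float = -0.2
    m_sample_sd: float = 0.15
    m_probe_sd: float = 0.3
    m_noise_sd: float = 0.2
    n_ambiguous_probes: int = 8
    n_unassigned_probes: int = 10
    tss_flank_bp: int = 500

    # survival
    baseline_hazard: float = 0.0005  # events per day
    burden_log_hazard: float = -0.7  # per SD of burden; negative = protective
    censoring_rate: float = 0.2

    # fragile sites
    cfs_per_chrom: int = 12
    cfs_width_bp: int = 20_000

    def __post_init__(self) -> None:
        rates = {
            "polymorphic_carrier_prob": self.polymorphic_carrier_prob,
            "fn_rate_primary": self.fn_rate_primary,
            "fn_rate_secondary": self.fn_rate_secondary,
            "fp_rate_primary": self.fp_rate_primary,
            "fp_rate_secondary": self.fp_rate_secondary,
            "censoring_rate": self.censoring_rate,
            "gc_content": self.gc_content,
        }
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.caller_jitter_bp >= self.consensus_window_bp:
            raise ValueError(
                "caller jitter must stay below the consensus window "
                f"({self.caller_jitter_bp} >= {self.consensus_window_bp})"
            )
        if not (0 <= self.tsd_mode <= self.tsd_max):
            raise ValueError("tsd_mode must lie within [0, tsd_max]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CohortTruth:
    """Planted ground truth, sufficient to recompute every downstream summary."""

    insertions: pd.DataFrame  # one row per (patient, site) planted event
    patients: pd.DataFrame  # patient_id, true_burden
    probes: pd.DataFrame  # probe_id, family, subfamily, planted_shift
    params: SimParams


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named substream: reproducible regardless of generation order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _chrom_names(params: SimParams) -> list[str]:
    return [f"chr{i + 1}" for i in range(params.n_chroms)]


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def simulate_genes(params: SimParams, seed: int) -> GeneSet:
    """Non-overlapping gene walk plus a few deliberately overlapping pairs."""
    rng = _rng(seed, "genes")
    genes: list[Gene] = []
    idx = 0
    for chrom in _chrom_names(params):
        pos = 2_000
        placed = 0
        while placed < params.genes_per_chrom:
            gap = int(rng.exponential(600)) + 200
            span = int(rng.lognormal(np.log(1500), 0.9)) + 200
            span = min(span, 40_000)
            start = pos + gap
            end = start + span
            if end > params.chrom_length - 2_000:
                break
            idx += 1
            genes.append(_make_gene(idx, chrom, start, end, rng))
            pos = end
            placed += 1
    # overlapping pairs exercise the multi-gene context flag
    rng2 = _rng(seed, "genes-overlap")
    for chrom in _chrom_names(params):
        candidates = [g for g in genes if g.chrom == chrom]
        for g in rng2.choice(candidates, size=min(3, len(candidates)), replace=False):
            rep = g.representative
            span = rep.span
            start = rep.start + span // 2
            end = start + max(400, span)
            if end > params.chrom_length - 1_000:
                continue
            idx += 1
            genes.append(_make_gene(idx, chrom, start, end, rng2))
    return GeneSet(genes)


def _make_gene(idx: int, chrom: str, start: int, end: int, rng) -> Gene:
    gene_id = f"GENE{idx:05d}"
    strand = "+" if rng.random() < 0.5 else "-"
    span = end - start
    n_exons = int(rng.integers(2, 6))
    exon_w = max(30, span // (10 * n_exons))
    exons = []
    for i in range(n_exons):
        s = start + (span * i) // n_exons
        e = min(s + exon_w, end)
        if e > s:
            exons.append((s, e))
    cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
    cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
    cds = []
    if cds_end > cds_start:
        for s, e in exons:
            cs, ce = max(s, cds_start), min(e, cds_end)
            if ce > cs:
                cds.append((cs, ce))
    transcripts = [
        Transcript(f"{gene_id}.t1", start, end, exons=list(exons), cds=list(cds))
    ]
    if rng.random() < 0.3 and span > 600:
        # a shorter minor isoform; the representative stays t1
        transcripts.append(
            Transcript(
                f"{gene_id}.t2",
                start,
                start + span // 2,
                exons=[(s, e) for s, e in exons if e <= start + span // 2],
            )
        )
    return Gene(gene_id, gene_id, chrom, strand, transcripts)


def simulate_repeats(params: SimParams, seed: int) -> RepeatSet:
    """Plant methylation-bearing repeats: full-length and truncated LINE-1,
    Alu, plus two constructed ambiguities (overlapping TSS windows of
    different Alu subfamilies, and an Alu next to a LINE-1 5' end)."""
    rng = _rng(seed, "repeats")
    elements: list[RepeatElement] = []
    chroms = _chrom_names(params)
    walk = {c: 10_000 for c in chroms}

    def place(chrom: str, length: int, subfamily: str, gap: int = 2_500) -> RepeatElement:
        start = walk[chrom] + gap
        el = RepeatElement(
            chrom=chrom,
            start=start,
            end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            subfamily=subfamily,
        )
        walk[chrom] = el.end
        if el.end > params.chrom_length - 2_000:
            raise ValueError("repeat annotation exceeds genome capacity")
        return el

    for sub in METH_SUBFAMILIES[TEFamily.LINE1]:
        for k in range(2):
            chrom = chroms[k % len(chroms)]
            elements.append(place(chrom, int(rng.integers(6000, 6500)), sub))
        # a truncated copy of each lineage, excluded by the full-length filter
        elements.append(place(chroms[0], int(rng.integers(800, 3000)), sub))
    for sub in METH_SUBFAMILIES[TEFamily.ALU]:
        for k in range(3):
            chrom = chroms[k % len(chroms)]
            elements.append(place(chrom, int(rng.integers(280, 320)), sub))

    # window-overlap construct: two Alu subfamilies 600 bp apart ('+' strands
    # so both windows anchor at start)
    s1 = walk[chroms[0]] + 3_000
    elements.append(
        RepeatElement(chroms[0], s1, s1 + 300, "+", "AluYa5")
    )
    elements.append(
        RepeatElement(chroms[0], s1 + 600, s1 + 900, "+", "AluYb8")
    )
    # cross-family construct: Alu window overlapping a full-length L1 window
    s2 = s1 + 600 + 300 + 3_000
    elements.append(RepeatElement(chroms[0], s2, s2 + 6200, "+", "L1HS"))
    elements.append(RepeatElement(chroms[0], s2 + 400, s2 + 700, "+", "AluSx"))
    walk[chroms[0]] = s2 + 6200
    return RepeatSet(sorted(elements, key=lambda e: (e.chrom, e.start, e.subfamily)))


def simulate_cfs(params: SimParams, seed: int) -> dict[str, list[tuple[int, int]]]:
    rng = _rng(seed, "cfs")
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom in _chrom_names(params):
        n_slots = max(1, params.chrom_length // (params.cfs_width_bp * 2) - 1)
        slots = np.sort(
            rng.choice(
                n_slots,
                size=min(params.cfs_per_chrom, n_slots),
                replace=False,
            )
        )
        intervals[chrom] = [
            (int(s) * params.cfs_width_bp * 2, int(s) * params.cfs_width_bp * 2 + params.cfs_width_bp)
            for s in slots
        ]
    return intervals


# ---------------------------------------------------------------------------
# Insertion truth
# ---------------------------------------------------------------------------


class _SitePlacer:
    """Rejection sampler enforcing minimum separation between sites."""

    def __init__(self, params: SimParams, genes: GeneSet, rng) -> None:
        self.params = params
        self.rng = rng
        self.chroms = _chrom_names(params)
        self.margin = 600  # keep flanking/TSS windows inside the contig
        self.shared: dict[str, list[int]] = {c: [] for c in self.chroms}
        gene_list = list(genes)
        self.genes = gene_list
        weights = np.array(
            [g.representative.span ** params.gene_length_bias_exponent for g in gene_list],
            dtype=float,
        )
        self.gene_p = weights / weights.sum()
        from intervaltree import IntervalTree

        self.gene_trees: dict[str, IntervalTree] = {}
        for g in gene_list:
            rep = g.representative
            self.gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                rep.start, rep.end, g.gene_id
            )

    def _ok(self, chrom: str, pos: int, private: dict[str, list[int]]) -> bool:
        sep = self.params.min_site_separation_bp
        for pool in (self.shared[chrom], private.get(chrom, [])):
            i = bisect.bisect_left(pool, pos)
            if i < len(pool) and abs(pool[i] - pos) < sep:
                return False
            if i > 0 and abs(pool[i - 1] - pos) < sep:
                return False
        return True

    def _record(self, chrom: str, pos: int, store: dict[str, list[int]]) -> None:
        bisect.insort(store.setdefault(chrom, []), pos)

    def sample(
        self, private: dict[str, list[int]], shared: bool = False
    ) -> tuple[str, int, str]:
        """Return (chrom, 1-based pos, gene_id-or-'') respecting separation."""
        p = self.params
        for _ in range(2000):
            if self.rng.random() < p.p_genic:
                gi = self.rng.choice(len(self.genes), p=self.gene_p)
                gene = self.genes[gi]
                rep = gene.representative
                p0 = int(self.rng.integers(rep.start, rep.end))
                chrom, gene_id = gene.chrom, gene.gene_id
            else:
                chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
                p0 = int(
                    self.rng.integers(self.margin, p.chrom_length - self.margin)
                )
                if self.gene_trees.get(chrom) and self.gene_trees[chrom][p0]:
                    continue
                gene_id = ""
            if p0 < self.margin or p0 > p.chrom_length - self.margin:
                continue
            if not self._ok(chrom, p0, private):
                continue
            self._record(chrom, p0, self.shared if shared else private)
            return chrom, p0 + 1, gene_id
        raise ValueError(
            "insertion count exceeds genome capacity (cannot place a site "
            f"with {p.min_site_separation_bp} bp separation)"
        )


def _draw_family(rng, params: SimParams) -> tuple[str, str]:
    fams = sorted(params.family_weights)
    w = np.array([params.family_weights[f] for f in fams], dtype=float)
    fam = fams[int(rng.choice(len(fams), p=w / w.sum()))]
    subs = SUBFAMILIES[TEFamily(fam)]
    return fam, subs[int(rng.integers(len(subs)))]


def _draw_tsd_length(rng, params: SimParams) -> int:
    """Discretized Laplace on 0..tsd_max, peaked at the configured mode."""
    support = np.arange(params.tsd_max + 1)
    w = np.exp(-np.abs(support - params.tsd_mode) / params.tsd_scale)
    return int(rng.choice(support, p=w / w.sum()))


def simulate_insertion_truth(
    params: SimParams, genes: GeneSet, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant every insertion event; returns (truth table, catalog frame).

    The catalog holds the polymorphic pool with independent uniform
    ±catalog_jitter_bp coordinate noise, mimicking cross-study imprecision.
    """
    rng = _rng(seed, "insertions")
    placer = _SitePlacer(params, genes, rng)

    pool = []
    for s in range(params.n_polymorphic_sites):
        chrom, pos, gene_id = placer.sample({}, shared=True)
        fam, sub = _draw_family(rng, params)
        while fam == "HERVK":  # the population catalog reports no HERV-K
            fam, sub = _draw_family(rng, params)
        pool.append(
            {
                "site_id": f"POLY{s:04d}",
                "chrom": chrom,
                "pos": pos,
                "te_family": fam,
                "subfamily": sub,
                "tsd_length": _draw_tsd_length(rng, params),
                "gene_id": gene_id,
            }
        )

    rows = []
    patients = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    for pid in patients:
        private: dict[str, list[int]] = {}
        shape = params.burden_dispersion_shape
        germline_rate = (
            float(rng.gamma(shape, params.germline_rate / shape))
            if shape > 0
            else params.germline_rate
        )
        for cls, rate in (
            ("germline", germline_rate),
            ("tumor_somatic", params.tumor_somatic_rate),
            ("normal_somatic", params.normal_somatic_rate),
        ):
            for _ in range(int(rng.poisson(rate))):
                chrom, pos, gene_id = placer.sample(private)
                fam, sub = _draw_family(rng, params)
                rows.append(
                    {
                        "patient_id": pid,
                        "chrom": chrom,
                        "pos": pos,
                        "te_family": fam,
                        "subfamily": sub,
                        "true_class": cls,
                        "tsd_length": _draw_tsd_length(rng, params),
                        "gene_id": gene_id,
                    }
                )
        carried = rng.random(len(pool)) < params.polymorphic_carrier_prob
        for site, c in zip(pool, carried):
            if c:
                rows.append(
                    {
                        "patient_id": pid,
                        "chrom": site["chrom"],
                        "pos": site["pos"],
                        "te_family": site["te_family"],
                        "subfamily": site["subfamily"],
                        "true_class": "polymorphic",
                        "tsd_length": site["tsd_length"],
                        "gene_id": site["gene_id"],
                    }
                )
    truth = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "chrom",
            "pos",
            "te_family",
            "subfamily",
            "true_class",
            "tsd_length",
            "gene_id",
        ],
    ).sort_values(["patient_id", "chrom", "pos"]).reset_index(drop=True)

    jitter = _rng(seed, "catalog").integers(
        -params.catalog_jitter_bp, params.catalog_jitter_bp + 1, size=len(pool)
    )
    catalog = pd.DataFrame(
        {
            "chrom": [s["chrom"] for s in pool],
            "pos": [max(1, s["pos"] + int(j)) for s, j in zip(pool, jitter)],
            "family": [s["te_family"] for s in pool],
            "subfamily": [s["subfamily"] for s in pool],
        }
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return truth, catalog


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_genome(
    params: SimParams, truth: pd.DataFrame, seed: int
) -> dict[str, str]:
    """Random-background genome with planted A/T excess around every site."""
    rng = _rng(seed, "genome")
    gc = params.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for chrom in _chrom_names(params):
        idx = rng.choice(4, size=params.chrom_length, p=probs)
        genome[chrom] = idx
    at_p = min(1.0, 0.5 + params.at_enrichment + (0.5 - gc))
    fl = params.at_flank_bp
    enrich_rng = _rng(seed, "genome-at")
    sites = truth[["chrom", "pos"]].drop_duplicates().sort_values(["chrom", "pos"])
    for row in sites.itertuples(index=False):
        p0 = row.pos - 1
        arr = genome[row.chrom]
        lo, hi = max(0, p0 - fl), min(len(arr), p0 + fl + 1)
        n = hi - lo
        is_at = enrich_rng.random(n) < at_p
        pick = enrich_rng.integers(0, 2, size=n)
        # A/T when is_at else C/G
        arr[lo:hi] = np.where(is_at, np.where(pick == 0, 0, 3), np.where(pick == 0, 1, 2))
    return {c: "".join(_BASES[v]) for c, v in genome.items()}


# ---------------------------------------------------------------------------
# Caller emission
# ---------------------------------------------------------------------------

_SAMPLE_CLASSES = {
    Tissue.TUMOR: ("germline", "polymorphic", "tumor_somatic"),
    Tissue.NORMAL: ("germline", "polymorphic", "normal_somatic"),
}


def emit_caller_calls(
    truth: pd.DataFrame,
    patient_id: str,
    tissue: Tissue,
    caller: Caller,
    params: SimParams,
    rng: np.random.Generator,
) -> list[TECall]:
    """One caller's call set for one sample, with FN drops, FP spikes,
    positional jitter and CIs for the secondary caller, and TSD strings
    for the primary caller."""
    fn = params.fn_rate_primary if caller is Caller.PRIMARY else params.fn_rate_secondary
    fp = params.fp_rate_primary if caller is Caller.PRIMARY else params.fp_rate_secondary
    sub = truth[
        (truth["patient_id"] == patient_id)
        & truth["true_class"].isin(_SAMPLE_CLASSES[tissue])
    ]
    sample_id = f"{patient_id}_{tissue.value}"
    calls: list[TECall] = []
    j = params.caller_jitter_bp
    for row in sub.itertuples(index=False):
        if rng.random() < fn:
            continue
        if caller is Caller.PRIMARY:
            pos = int(row.pos)
            tsd = None
            if row.tsd_length > 0:
                tsd = "".join(_BASES[rng.integers(0, 4, size=int(row.tsd_length))])
            calls.append(
                TECall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    tissue=tissue,
                    chrom=row.chrom,
                    pos=pos,
                    te_family=TEFamily(row.te_family),
                    subfamily=row.subfamily,
                    tsd_sequence=tsd,
                    caller=caller,
                )
            )
        else:
            pos = max(1, int(row.pos) + int(rng.integers(-j, j + 1)) if j else int(row.pos))
            calls.append(
                TECall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    tissue=tissue,
                    chrom=row.chrom,
                    pos=pos,
                    te_family=TEFamily(row.te_family),
                    subfamily=row.subfamily,
                    caller=caller,
                    ci_lo=max(1, pos - j),
                    ci_hi=pos + j,
                )
            )
    n_fp = int(rng.binomial(len(sub), fp)) if len(sub) else 0
    chroms = _chrom_names(params)
    for _ in range(n_fp):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(600, params.chrom_length - 600))
        fam, subf = _draw_family(rng, params)
        kw = {}
        if caller is Caller.SECONDARY:
            kw = {"ci_lo": max(1, pos - j), "ci_hi": pos + j}
        calls.append(
            TECall(
                patient_id=patient_id,
                sample_id=sample_id,
                tissue=tissue,
                chrom=chrom,
                pos=pos,
                te_family=TEFamily(fam),
                subfamily=subf,
                caller=caller,
                **kw,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.te_family.value))
    return calls


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def simulate_methylation(
    params: SimParams, repeats: RepeatSet, seed: int
) -> tuple[pd.DataFrame, list[ProbeRecord], pd.DataFrame, pd.DataFrame]:
    """Probes inside TE TSS windows plus a planted tumor M shift.

    Returns ``(beta, probes, sample_groups, probe_truth)``.  Young-LINE-1
    probes carry the full planted tumor hypomethylation; all Alu probes a
    milder one; everything else no shift.
    """
    from .methylation import age_category, select_full_length_line1, te_tss_windows

    rng = _rng(seed, "methylation")
    chrom_sizes = {c: params.chrom_length for c in _chrom_names(params)}
    line1 = select_full_length_line1(repeats)
    alu = [el for el in repeats if el.family is TEFamily.ALU]
    l1_windows = te_tss_windows(line1, params.tss_flank_bp, chrom_sizes)
    alu_windows = te_tss_windows(alu, params.tss_flank_bp, chrom_sizes)

    from intervaltree import IntervalTree

    tree: dict[str, IntervalTree] = {}
    memberships: dict[str, set] = {}
    for w in l1_windows + alu_windows:
        tree.setdefault(w.chrom, IntervalTree()).addi(
            w.start, w.end, (w.family.value, w.subfamily)
        )

    def window_members(chrom: str, p0: int) -> set:
        t = tree.get(chrom)
        return {iv.data for iv in t[p0]} if t else set()

    probes: list[ProbeRecord] = []
    truth_rows = []
    pid = 0

    def add_probe(chrom: str, p0: int, family: str, subfamily: str, shift: float):
        nonlocal pid
        pid += 1
        regions_pool = ["TSS1500", "TSS200", "5UTR", "FirstExon", "Body", "3UTR"]
        k = int(rng.integers(1, 3))
        regions = tuple(
            sorted(rng.choice(regions_pool, size=k, replace=False).tolist())
        )
        probes.append(
            ProbeRecord(
                probe_id=f"cg{pid:07d}",
                chrom=chrom,
                pos=p0 + 1,
                region_annotations=regions,
            )
        )
        truth_rows.append(
            {
                "probe_id": f"cg{pid:07d}",
                "family": family,
                "subfamily": subfamily,
                "planted_shift": shift,
            }
        )

    # unambiguous probes: sample positions per window whose membership is unique
    for w in sorted(l1_windows + alu_windows, key=lambda w: (w.chrom, w.start, w.subfamily)):
        placed = 0
        tries = 0
        per_window = max(2, params.probes_per_subfamily // 3)
        while placed < per_window and tries < 200:
            tries += 1
            p0 = int(rng.integers(w.start, w.end))
            mem = window_members(w.chrom, p0)
            if mem != {(w.family.value, w.subfamily)}:
                continue
            shift = 0.0
            if w.family is TEFamily.LINE1:
                if age_category(w.subfamily, TEFamily.LINE1) == "young":
                    shift = params.m_shift_young_line1
            else:
                shift = params.m_shift_alu
            add_probe(w.chrom, p0, w.family.value, w.subfamily, shift)
            placed += 1

    # ambiguous probes: pairwise overlap regions of windows with distinct
    # (family, subfamily) identities
    zone_set = set()
    for chrom in sorted(tree):
        for iv in sorted(tree[chrom]):
            for other in tree[chrom].overlap(iv.begin, iv.end):
                if other.data == iv.data:
                    continue
                lo, hi = max(iv.begin, other.begin), min(iv.end, other.end)
                if hi > lo:
                    zone_set.add((chrom, lo, hi))
    ambiguous_zones = sorted(zone_set)
    for i in range(params.n_ambiguous_probes):
        if not ambiguous_zones:
            break
        chrom, lo, hi = ambiguous_zones[i % len(ambiguous_zones)]
        for _ in range(200):
            p0 = int(rng.integers(lo, hi))
            if len(window_members(chrom, p0)) > 1:
                add_probe(chrom, p0, "ambiguous", "ambiguous", 0.0)
                break

    # probes outside every window
    chroms = _chrom_names(params)
    for _ in range(params.n_unassigned_probes):
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            p0 = int(rng.integers(1_000, params.chrom_length - 1_000))
            if not window_members(chrom, p0):
                add_probe(chrom, p0, "none", "none", 0.0)
                break

    probe_truth = pd.DataFrame(truth_rows)
    tumor_samples = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    control_samples = [f"CTRL{i + 1}" for i in range(params.n_control_samples)]
    samples = tumor_samples + control_samples
    groups = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["tumor"] * len(tumor_samples) + ["control"] * len(control_samples),
        }
    )
    n_p, n_s = len(probes), len(samples)
    probe_eff = rng.normal(0.0, params.m_probe_sd, size=n_p)
    sample_eff = rng.normal(0.0, params.m_sample_sd, size=n_s)
    noise = rng.normal(0.0, params.m_noise_sd, size=(n_p, n_s))
    shift = probe_truth["planted_shift"].to_numpy()[:, None] * np.array(
        [1.0 if s in tumor_samples else 0.0 for s in samples]
    )[None, :]
    m = params.m_base + probe_eff[:, None] + sample_eff[None, :] + shift + noise
    beta = 1.0 / (1.0 + np.power(2.0, -m))
    beta_df = pd.DataFrame(
        beta, index=[p.probe_id for p in probes], columns=samples
    )
    return beta_df, probes, groups, probe_truth


# ---------------------------------------------------------------------------
# Clinical / expression
# ---------------------------------------------------------------------------


def simulate_clinical(
    burdens: dict[str, int], params: SimParams, rng: np.random.Generator
) -> list[ClinicalRecord]:
    """Event-free survival from an exponential proportional-hazards model.

    Hazard for patient i is ``h0 * exp(beta * z_i)`` with z the
    cohort-standardized burden; censoring is independent exponential with
    rate tuned to the requested censoring fraction.
    """
    h0 = params.baseline_hazard
    if h0 <= 0:
        raise ValueError(f"baseline hazard must be > 0, got {h0}")
    pids = sorted(burdens)
    b = np.array([burdens[p] for p in pids], dtype=float)
    sd = b.std(ddof=1)
    z = (b - b.mean()) / sd if sd > 0 else np.zeros_like(b)
    hazards = h0 * np.exp(params.burden_log_hazard * z)
    times = rng.exponential(1.0 / hazards)
    c = params.censoring_rate
    if c >= 1.0:
        events = np.zeros(len(pids), dtype=int)
        obs = times
    elif c <= 0.0:
        events = np.ones(len(pids), dtype=int)
        obs = times
    else:
        cens_rate = h0 * c / (1.0 - c)
        cens = rng.exponential(1.0 / cens_rate, size=len(pids))
        events = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    obs = np.maximum(obs, 1.0)
    statuses = ["localized", "metastatic"]
    sites = ["leg", "arm", "pelvis"]
    records = []
    for i, pid in enumerate(pids):
        records.append(
            ClinicalRecord(
                patient_id=pid,
                efs_time=float(np.round(obs[i], 1)),
                event=int(events[i]),
                age_dx=float(np.round(np.clip(rng.normal(15, 5), 3, 70), 1)),
                disease_status_dx=statuses[int(rng.random() < 0.25)],
                primary_site=sites[int(rng.choice(3, p=[0.6, 0.2, 0.2]))],
            )
        )
    return records


def simulate_expression(params: SimParams, seed: int) -> pd.DataFrame:
    rng = _rng(seed, "expression")
    pids = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    cols = [
        "expr_LINE1_young",
        "expr_LINE1_intermediate",
        "expr_LINE1_old",
        "expr_ALU_young",
        "expr_ALU_intermediate",
        "expr_ALU_old",
    ]
    data = rng.normal(5.0, 1.0, size=(len(pids), len(cols)))
    return pd.DataFrame(data, index=pd.Index(pids, name="patient_id"), columns=cols)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def generate_cohort(params: SimParams, seed: int, out_dir) -> CohortTruth:
    """Write the complete input bundle and return the truth ledger.

    Deterministic: identical (params, seed) produce a byte-identical
    bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "calls").mkdir(exist_ok=True)

    genes = simulate_genes(params, seed)
    repeats = simulate_repeats(params, seed)
    cfs = simulate_cfs(params, seed)
    truth, catalog = simulate_insertion_truth(params, genes, seed)
    genome = simulate_genome(params, truth, seed)

    rio.write_fasta(genome, out / "genome.fa")
    rio.write_gene_models(genes, out / "genes.gff3")
    rio.write_repeats(repeats, out / "repeats.tsv")
    rio.write_intervals(cfs, out / "cfs.bed")
    rio.write_catalog(catalog, out / "catalog.bed")

    contigs = {c: params.chrom_length for c in _chrom_names(params)}
    pids = [f"P{i + 1:03d}" for i in range(params.n_patients)]
    for pid in pids:
        for tissue in (Tissue.TUMOR, Tissue.NORMAL):
            for caller in (Caller.PRIMARY, Caller.SECONDARY):
                rng = _rng(seed, f"calls/{pid}/{tissue.value}/{caller.value}")
                calls = emit_caller_calls(truth, pid, tissue, caller, params, rng)
                rio.write_mei_calls(
                    calls,
                    out / "calls" / f"{pid}_{tissue.value}_{caller.value}.vcf",
                    contigs,
                )

    beta, probes, groups, probe_truth = simulate_methylation(params, repeats, seed)
    rio.write_beta_and_manifest(beta, probes, out / "beta.csv", out / "manifest.csv")
    groups.to_csv(out / "sample_groups.csv", index=False)

    specific = truth[truth["true_class"].isin(["germline", "tumor_somatic"])]
    burdens = {pid: int((specific["patient_id"] == pid).sum()) for pid in pids}
    clinical = simulate_clinical(burdens, params, _rng(seed, "clinical"))
    rio.write_clinical(clinical, out / "clinical.csv")
    simulate_expression(params, seed).to_csv(out / "expression.csv")

    patients = pd.DataFrame(
        {"patient_id": pids, "true_burden": [burdens[p] for p in pids]}
    )
    truth.to_csv(out / "truth_insertions.tsv", sep="\t", index=False)
    patients.to_csv(out / "truth_patients.tsv", sep="\t", index=False)
    probe_truth.to_csv(out / "truth_probes.tsv", sep="\t", index=False)
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
    return CohortTruth(insertions=truth, patients=patients, probes=probe_truth, params=params)
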