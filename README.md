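# retroscope

Post-calling analysis of transposable-element (TE) insertions in paired
tumor/normal cohorts.

Mobile-element-insertion (MEI) callers emit noisy, partially overlapping
call sets, and raw calls mix three very different things: insertions
segregating in the general population, inherited (germline) insertions
private to a patient, and true somatic events.  `retroscope` implements
the standard post-calling chain that separates them and characterizes
what remains:

1. **Two-caller consensus** — calls from a precise caller (MELT-style:
   exact breakpoints plus target-site-duplication sequences) and an
   imprecise caller (Mobster-style: position plus confidence interval)
   are reconciled one-to-one when they share chromosome and TE family
   (LINE-1, Alu, SVA, HERV-K) within 100 bp; the precise caller's
   coordinate becomes the consensus position.
2. **Polymorphic filtering** — a call with a same-family population-catalog
   entry (e.g., the 1000 Genomes phase-3 MEI release) within *d* bp is
   removed; a scan table of remaining counts over a distance grid
   supports choosing *d* (default 20 bp).  HERV-K is never filtered,
   since the population catalog reports no HERV-K insertions.
3. **Germline/somatic classification** — within each patient, a tumor
   call paired with a normal call inside 100 bp is germline (reported
   once, at the tumor coordinate); unmatched tumor calls are
   tumor-specific somatic, unmatched normal calls normal-specific
   somatic.
4. **Insertional features** — TSD length histogram (genuine
   LINE-1-mediated events cluster near 15 bp), A/C/G/T composition in
   ±50 bp flanks (AT-rich target preference), genomic context against
   representative (longest) transcript isoforms, gene-length
   stratification, common-fragile-site overlap, recurrently hit genes
   (≥3 patients), cancer-gene-list intersection, and exon proximity of
   intronic insertions (≤100 bp).
5. **TE-promoter methylation** — 450K-style probes mapped to ±500 bp
   windows around the most-5′ end of Alu and full-length (≥5.9 kb)
   LINE-1 elements; M-values (M = log2 β/(1−β)) averaged per subfamily
   per sample, grouped into evolutionary ages (L1HS+L1PA / L1P / L1M;
   AluY / AluS / other Alu), and compared tumor vs control with the
   unpaired two-sample Wilcoxon rank-sum test.
6. **Survival association** — standardized TE-activity features
   (expression and methylation by age category, insertion burden) plus
   clinical covariates enter a Spearman correlation matrix and a Cox
   proportional-hazards model of event-free survival (Efron ties,
   likelihood-ratio test), with Kaplan–Meier curves and a log-rank test
   stratifying patients at a burden of 100 insertions (burden > 100 is
   the high group).

Because the real cohorts this kind of analysis runs on are controlled
access, the package ships a first-class synthetic-cohort generator
(`retroscope.simulate`) that emits every input — genome FASTA, GFF3 gene
models, repeat annotation, fragile-site BED, polymorphic catalog,
per-sample two-caller VCFs, beta-value matrices, clinical table — with a
machine-readable truth ledger, so every stage is testable for exact or
statistical recovery.  See `docs/methods.md` for the generative model.

## Worked example

Simulate a 39-patient cohort and run the full pipeline:

```sh
retroscope simulate --seed 1 --out demo_bundle
# wrote bundle to demo_bundle: 5907 planted insertions, 39 patients, 180 probes

retroscope run-all --bundle demo_bundle --out demo_reports --seed 1
# reports written to demo_reports
# TSD length mode: 15 bp
# Cox LRT = 29.84 on 17 df, p = 0.0275, n = 39, events = 23
```

The TSD mode of 15 bp recovers the generator's planted
target-site-duplication distribution — the hallmark length of
LINE-1-machinery integration.  The Cox model (17 coefficients: burden,
six expression and six methylation age-category features, age at
diagnosis, and dummy-encoded disease status and primary site) rejects
the null overall, driven by the planted protective burden effect.
Among the report tables:

```
$ head -2 demo_reports/classification_totals.tsv
germline  tumor_somatic  normal_somatic  total  n_patients  ...
3272      222            62              3556   39          ...
```

Most patient-specific insertions are germline, with a small
tumor-somatic minority — the structure the classification is designed to
resolve.  `demo_reports/polymorphic_scan.tsv` shows the distance scan:
at 0 bp only exact catalog coincidences are removed; from 5 bp on (the
catalog's planted coordinate jitter) all polymorphic insertions are
gone, and counts stay flat to 100 bp.

Every stage is also exposed as a library function
(`match_consensus`, `filter_polymorphic`, `classify_patient`,
`beta_to_m`, `fit_cox_efs`, ...) and as individual CLI subcommands
(`consensus`, `specificity`, `classify`).

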