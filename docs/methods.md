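# Methods

This note documents the models and procedures implemented in
`retroscope`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical choices a
maintainer would want written down.

## Coordinate conventions

External formats keep their native conventions — VCF and GFF3 are
1-based, BED is 0-based half-open — and are converted at the I/O
boundary.  All internal interval arithmetic is 0-based half-open;
insertion positions stay 1-based points because they travel to and from
VCF.  Chromosome-name matching is exact-string, with an opt-in config
switch to strip `chr` prefixes; the default is strict so that mixed
annotation builds fail loudly rather than silently mismatching.

## Consensus matching

Two callers describe the same event when chromosome and TE family agree
and |Δpos| ≤ `consensus_window_bp` (default 100, inclusive).  Matching is
one-to-one greedy nearest-first: candidate pairs are sorted by |Δpos|,
ties broken by smaller primary then smaller secondary position, and
accepted while both calls are unconsumed.  On instances whose optimal
matching is unique, this equals the minimum-total-distance
maximum-cardinality bipartite assignment (validated in the test suite
against the Hungarian algorithm); greedy was chosen because it is
deterministic, linear to reason about, and matching ambiguity only
arises when distinct insertions sit within one window of each other,
where no distance criterion can be trusted anyway.  Family-level (not
subfamily-level) agreement is required: subfamily annotation differs
systematically between callers, so the consensus keeps the primary
caller's subfamily and logs disagreements.  The primary caller's
position is the consensus coordinate because it resolves breakpoints at
base precision while the secondary caller reports an interval.

## Polymorphic filtering

A call is polymorphic if ANY same-family catalog entry on its chromosome
lies within `polymorphic_distance_bp` (default 20).  This is filtering,
not pairing: catalog entries are not consumed, so two nearby calls can
both be removed by one entry.  The distance scan
(`scan_filter_distances`, default grid 0–100 by 5) reports remaining
counts so the threshold can be chosen by inspection; the threshold is a
configuration value, never auto-selected, because any automatic elbow
criterion would impose a model the underlying procedure does not state.
HERV-K calls always pass: the population catalog contains no HERV-K
entries, and hard-coding the exemption keeps the scan table and the
filter cardinalities consistent for every family.

## Germline/somatic classification

Per patient, tumor and normal patient-specific calls are paired with the
same greedy matcher inside `somatic_window_bp` (default 100).  A matched
pair is one germline record at the tumor coordinate (the pair describes
one inherited insertion; the tumor coordinate keeps downstream
tumor-centric feature analyses consistent); unmatched calls become
tumor-specific or normal-specific somatic records.  Both tissues are
filtered against the catalog *before* classification, mirroring the
patient-specific-first order of operations.  Summary tables report raw
call conservation (each germline record absorbs two calls) and the
per-patient tumor-somatic range among carriers.

## Insertional features

* **TSD histogram** — lengths of available TSD sequences; mode ties break
  to the smaller length; calls without a TSD are counted, not dropped
  silently.
* **Flanking composition** — per-position A/C/G/T fractions over
  ±`flank_bp` (default 50) on the reference strand (no orientation
  flipping: insertion strand is not modeled).  N bases leave the
  denominator per position; windows truncated by a contig edge exclude
  the site and count it.
* **Genomic context** — each insertion is evaluated against the
  representative transcript (maximal genomic span, ties to the
  lexicographically smallest transcript id) of every overlapped gene.
  Within a gene the precedence is CDS > 5′UTR > 3′UTR > intron; UTRs are
  exonic sequence outside the CDS span, strand-resolved.  Positions
  inside a transcript that hit no exon — and exons of non-coding
  transcripts, which the five-label vocabulary cannot place — count as
  intronic.  Across genes the insertion's summary label is the
  highest-precedence hit; overlapping ≥2 genes sets a flag reported
  separately so multi-gene insertions are tallied once.
* **Percentages** are rounded half-up to 2 decimals, matching the
  printed-table convention; summary percentages therefore total
  100.00 ± 0.05.
* **Gene length, CFS, recurrence** — a gene is "inserted" if any
  insertion overlaps its representative transcript; fragile-site
  membership is point-in-half-open-interval; a patient counts once per
  gene regardless of multiplicity, and recurrence requires
  ≥ `recurrence_min_patients` (default 3) patients.
* **Exon proximity** — for intronic insertions, the minimum distance to
  any exon boundary of the host representative transcript, inclusive at
  `max_dist_bp` (default 100); a base immediately after an exon end is
  at distance 1.

## TE-promoter methylation

Beta values are clamped to [1e−6, 1−1e−6] before M = log2(β/(1−β)),
which is undefined at the endpoints.  Full-length LINE-1 defaults to
≥ 5,900 bp — slightly permissive relative to the canonical ~6 kb intact
element, because genuine full-length copies carry small indels; the
threshold is configurable.  TSS windows are ±`tss_flank_bp` (default
500) around the most-5′ end (start for `+` elements, end for `−`),
clamped at contig bounds with a truncation flag.  Probe membership uses
the single manifest CpG coordinate, not the 50-bp probe extent, since
manifests provide one coordinate.  A probe inside windows of two
distinct Alu subfamilies is excluded (`multi_subfamily`); inside both an
Alu and a LINE-1 window, excluded (`cross_family`, the conservative
choice for an ambiguity the aggregation cannot attribute); multiple
windows of one subfamily collapse to a single assignment.  Per-subfamily
per-sample means are arithmetic means of assigned probes' M; age
categories (LINE-1: L1HS+L1PA young, other L1P intermediate, L1M old;
Alu: AluY young, AluS intermediate, remaining Alu plus FLAM/FRAM old)
aggregate as unweighted means over subfamily means, so probe-rich
subfamilies do not dominate a category.  Group comparisons use the
unpaired two-sample Wilcoxon rank-sum test: exact enumeration when both
groups have n ≤ 8 and no pooled ties, otherwise the normal approximation
with tie and continuity corrections; fully tied data return p = 1.

## Survival association

Features are standardized column-wise as (x − mean)/SD with the n−1
denominator; constant columns are dropped with a warning.  Categorical
clinical covariates are dummy-encoded against the most frequent level.
Spearman correlations use average ranks and the t-approximation with
df = n − 2; at very small n this approximation deviates from the exact
permutation null by up to ~0.05 for mid-range rho, so small-sample p
values near the significance boundary deserve caution.  The Cox model
maximizes the Efron partial likelihood (the default of the reference R
implementation); the global p-value is the likelihood-ratio test against
the null model with df equal to the number of coefficients.
Non-convergence and separation raise errors rather than returning
unstable estimates.  Kaplan–Meier stratification puts burden strictly
greater than `burden_threshold` (default 100) in the high group — the
boundary value goes low — with a two-group log-rank chi-square on 1 df.

## Synthetic cohort generator

The generator's defaults are the study conditions of the test suite:

* **Cohort** — 39 patients, each with paired tumor/normal call sets from
  two callers over a 2 × 600 kb genome at 50% GC.  The genome is a
  desk-scale stand-in: big enough that ~5,500 planted sites at ≥300 bp
  separation fit, small enough to generate in about a second.
* **Insertion classes** — per-patient germline counts are Poisson with a
  gamma-mixed mean (mean 80, dispersion shape 4), reproducing the long
  right tail of per-patient burden that makes a 100-insertion
  stratification meaningful; tumor-somatic mean 4 and normal-somatic
  mean 0.2 per patient keep the cohort germline-dominated with a small
  somatic minority.  Polymorphic insertions come from a shared pool of
  200 population sites carried with probability 0.3 and written to the
  catalog with independent uniform ±5 bp jitter, so the 20-bp filter is
  exercised against realistic cross-study coordinate noise.  Family mix:
  13% LINE-1, 80% Alu, 6% SVA, 1% HERV-K.
* **Placement** — a site is intronic-targeted with probability 0.5
  (gene chosen ∝ representative-transcript length^1, position uniform in
  the transcript) and intergenic otherwise; all sites within one patient,
  and all sites versus the polymorphic pool, keep ≥300 bp separation so
  that the noiseless cohort is exactly recoverable (no window can alias
  two distinct sites).
* **TSD lengths** — discretized Laplace on 0–30 bp with mode 15 and
  scale 2.  A peaked distribution was chosen over flatter unimodal
  shapes so that the sample mode is statistically identifiable at the
  few hundred observations a test-sized cohort yields.
* **Flanks** — bases within ±10 bp of every planted site are resampled
  with P(A or T) = 0.65 against the 0.5 background.
* **Caller noise** — the primary caller reports exact positions and TSD
  strings; the secondary caller jitters positions by U[−30, 30] and
  reports a CI of that half-width; each caller independently drops true
  calls at 1% and spikes false positives at 1% (binomial in the number
  of true calls).  1% reflects the residual error of consensus-grade
  callers; the noiseless configuration (0/0/0) is used wherever exact
  recovery is asserted.
* **Methylation** — probes are planted inside TSS windows of full-length
  LINE-1 (L1HS, L1PA2, L1PB1, L1M5) and Alu (AluYa5, AluYb8, AluSx,
  AluSp, AluJb) elements, plus constructed multi-subfamily and
  cross-family overlap zones and off-window probes to exercise every
  mapping branch.  M-values follow m = 2.0 + probe + sample + shift +
  noise (SDs 0.3 / 0.15 / 0.2), with a planted tumor shift of −0.5 M at
  young-LINE-1 probes and −0.2 M at Alu probes, then β = 2^m/(1+2^m).
* **Survival** — event times are exponential with hazard
  h₀·exp(β·z) where z is the cohort-standardized burden, h₀ = 5×10⁻⁴
  per day and β = −0.7 (protective, matching the direction of the
  burden–survival association the pipeline is designed to detect);
  censoring is independent exponential tuned to ~20%.
* **Determinism** — one seed; every component draws from a named
  substream (CRC-keyed `SeedSequence`), so identical (params, seed)
  yield byte-identical bundles regardless of call order.

What the generator does **not** emulate: read-level evidence (no
FASTQ/BAM, so caller noise is parametric rather than coverage-driven),
realistic human repeat landscapes and gene density, linkage between
polymorphic sites, expression–methylation coupling (expression features
are independent noise), and informative censoring.  Passing tests
therefore demonstrate that the *post-calling logic* is correct and that
planted signals of stated size are recovered at the stated sample sizes
— not that the upstream callers behave as modeled on real sequencing
data.

## Problem sizes in the tests and acceptance script

The default cohort (39 patients, ~5,500 planted events, 180 probes)
generates in ~2 s and runs through the full pipeline in ~1 s; the
noiseless recovery cohort uses 20 patients at ~100 insertions each;
statistical calibrations use 100–200 replicates at n = 40–200 patients.
These sizes make every recovery criterion statistically decidable while
keeping the whole suite under a minute of compute.

## Known limitations

* Greedy matching can differ from the global-optimal assignment when
  three or more calls crowd one window; such instances are logged only
  implicitly (via match distances) and are inherently ambiguous.
* The intronic label absorbs non-coding exonic hits; a richer vocabulary
  would need a non-coding-exon category.
* Spearman p-values are approximate at very small n (see above).
* The Cox stage requires enough patients per coefficient; with the full
  17-feature design, cohorts much below ~35 patients risk separation,
  which is reported as an error rather than silently regularized.
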