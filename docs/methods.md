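# Methods

## The burden-weighted binomial null

The quantity of interest for each driver mutation type (gene ×
mutation class) is the difference in carrier prevalence between
metastatic castration-resistant (mCRPC) and localized prostate cancer.
Because mCRPC genomes carry several-fold more mutations of every class,
a raw difference conflates driver-specific selection with global
burden. The null model asks how large a difference would arise if
mutations landed at random, in proportion to each sample's burden and
the gene's genomic footprint.

**Point mutations (coding and non-coding SNVs).** A sample with burden
b SNVs/Mbp against a reference of size G Mbp is modeled as N =
round(b·G) independent mutation events, each hitting a gene of coding
footprint g Mbp with probability g/G, so

P(≥1 hit) = 1 − (1 − g/G)^N,

evaluated in log space for numerical stability. G is the genome size
(default 3000 Mbp) for whole-genome-derived burdens and the exome size
(default 38 Mbp, a typical capture footprint) for exome-derived
burdens; each sample records which reference its burden refers to.

**Copy-number and structural classes.** Copy-number burden is the
percent genome altered (PGA). A literal per-base translation of the
SNV model degenerates: with millions of altered bases, P(hit)
saturates at 1 for any realistic PGA and the null stops discriminating
between samples. We therefore model each sample's copy-number burden
as M = max(1, round(PGA·G/λ)) segments of mean length λ (default
10 Mbp, matching the scale of recurrent prostate-cancer deletions,
configurable as `cna_segment_mbp`). A segment of length λ hits a gene
of span s bp when it overlaps it, with probability (s/10⁶ + λ)/G, so

P(≥1 hit) = 1 − (1 − (s/10⁶ + λ)/G)^M.

This preserves monotone burden-weighting without saturation.
Structural variants are also weighted by PGA through the same segment
process — SV counts track genomic instability, and per-sample SV
burdens are not separately available in the data model.

**Simulation.** For each mutation type, every iteration draws one
Bernoulli(P(hit)) per assayed sample and records the simulated
prevalence difference between states; the expected Δ is the mean over
iterations (default 100,000; the validation studies use 10,000, which
puts the Monte-Carlo standard error of the expected Δ well below the
assertion margins). Each mutation type consumes an independent random
substream derived from the run seed and a stable digest of the
mutation-type name, so results are independent of column order and of
which other mutation types are present.

**Empirical p-values.** Extremeness is measured two-sided about the
null mean: p = #{|sim − mean| ≥ |obs − mean|}/n_iter. For copy-number
classes the exceedance is halved — a copy-number aberration at a locus
can be a gain or a loss, and each direction is cataloged and tested as
its own mutation type. The floor 1/n_iter is applied after halving
(an empirical p of exactly zero is unreportable), and p is capped at 1.
Benjamini–Hochberg correction runs jointly across all non-flagged
mutation types.

A consequence worth stating plainly: under a pure null the plain
exceedance is uniform, so the halving rule doubles the copy-number
classes' type-I error at any nominal α (≈0.10 at α = 0.05). The
calibration study therefore quantifies type-I error on the non-halved
classes, and a separate study (`cna_halving_rate_study`) documents the
doubled copy-number rate. Both behaviors are deliberate consequences
of the published rule, not defects of the simulation.

## Prevalence and intervals

Per-class prevalence is carriers over assayed samples — samples
lacking an assay class are excluded from that class's denominator, not
counted as wild-type. Intervals are Wald, p ± 1.96·√(p(1−p)/n),
clipped to [0, 1]; the interval for a prevalence difference adds the
continuity correction (1/m + 1/n)/2 to the Wald half-width and clips
to [−1, 1].

Per-gene prevalence across classes defaults to `empirical_union`, the
exact proportion of samples carrying at least one mutation of any
class over the union of assayed samples. An `additive_literal` method
is retained that sums class proportions and subtracts all pairwise
*and* triple joint proportions (each on its own denominator, joints
read as "at least both"). The additive form is not standard
inclusion–exclusion — it subtracts the triple term rather than adding
it back, sitting 2·P(all three) below the exact union — and the exact
union is preferred wherever the matrix is available. The accompanying
error-propagation bookkeeping (per class, PE = √(CI_upper² +
CI_lower²); gene-level variance √(ΣPE_singles − ΣPE_joints)) is
evaluated literally; a negative radicand is reported as NaN with a
logged flag rather than silently clamped.

## Harmonization rules

- Copy-number calls: categorical inputs pool shallow and deep deletion
  to loss, gain and amplification to gain; log2 copy-number scores are
  thresholded inclusively (autosomes: gain ≥ 3, loss ≤ 1.65; X/Y:
  gain ≥ 1.4, loss ≤ 0.6); NaN means not assayed.
- SNV consequences retained: missense, stop gained/lost, splice
  donor/acceptor. Frameshift indels and synonymous changes are
  excluded; unrecognized terms are excluded conservatively with a
  logged warning.
- Coordinates are 0-based half-open internally; SEG input is treated
  as 1-based inclusive and converted on read.
- A copy-number segment hits a gene if it overlaps the gene span (or a
  pooled auxiliary locus, e.g. the AR enhancer upstream of the gene
  body, whose hits count toward AR) by ≥ 1 bp.
- SVs match by either breakpoint; entries may restrict subtypes
  (e.g. PTEN inversions separated from translocations/deletions);
  unrestricted entries accept any subtype, including unknown ones.
- Multiple hits of one gene and class in one sample collapse to a
  single "present": prevalence is per patient.

## Survival screening

Candidates are mutation types with differential q < 0.05 and localized
prevalence ≥ 5%. Each is fit in a univariable Cox
proportional-hazards model (partial likelihood via statsmodels PHReg)
of carrier status against the metastasis endpoint among localized
samples; BH correction runs across the candidate set only. Tie
handling defaults to Efron, which is less biased than Breslow when
monthly follow-up times produce many ties; Breslow is available.
Estimates with |log HR| > 20 or non-finite standard errors are
reported as convergence failures — this is the expected signature of
complete separation (e.g. a marker whose carriers all relapse), not a
numerical accident. Proportional hazards are checked by correlating
Schoenfeld residuals with event-time rank; a violated candidate falls
back to a log-rank p-value, noted in the report. Kaplan–Meier curves
and the log-rank test come from lifelines.

2×2 associations report the cross-product odds ratio with a Woolf
(log-normal) interval and a two-sided Fisher exact p; a zero cell
triggers the Haldane–Anscombe +0.5 correction for the OR and CI only,
never for the Fisher p.

## Scores

- **PGA**: union of altered bases over genome size; the adjusted form
  excludes a chromosome from both numerator and denominator (so it
  remains a true proportion — the exclusion exists to avoid a gene
  predicting its own chromosome's contribution).
- **Six-feature signature**: MYC gain, ATM SNV, chr7:61 Mbp
  translocation (present = 1); TCERGL1 promoter methylation below the
  cohort median and ACTL6B above it (the adverse directions); clinical
  T category cT2c = 1, cT1/cT2a/b = 0. Samples missing any feature
  are flagged non-informative and excluded. The 0–6 sum is the
  regression covariate; the median-dichotomized high/low bin is for
  display.
- **CCP score**: mean log2 abundance over the 31-gene
  cell-cycle-progression panel minus the mean over 15 housekeeping
  genes; exactly invariant under a constant shift of all genes. Gene
  panels are supplied via configuration, not hard-coded.
- **Youden cutpoint**: threshold over observed values maximizing
  sensitivity + specificity − 1, ties broken toward the lower
  threshold; direction (≥ or ≤ calls positive) is explicit.
- **Stratification**: median halves (boundary value → low) or
  quartiles (boundary → lower bin); all-tied input collapses to one
  bin with a warning.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per-state
log-normal SNV burdens (medians 1.0 and 4.5 SNVs/Mbp for localized and
metastatic disease, log-sd 0.5) and Beta-distributed PGA (means 5% and
25%) — values in the range reported for sequenced prostate-cancer
cohorts; a driver catalog with realistic footprints (coding footprints
1–4 kb, gene spans 50–300 kb); mutation presence drawn from the same
per-sample hit probabilities the null model computes, plus a planted
additive excess δ_g in the metastatic state (additive on the
probability scale so planted effects are directly comparable to
adjusted Δ); exponential proportional-hazards outcome times with
per-gene planted log hazard ratios and independent uniform censoring
whose horizon is solved by bisection to match the configured censoring
rate; and RNA/methylation values for a target gene in which
copy-number loss lowers RNA and raises promoter methylation, with the
RNA–methylation coupling coefficient calibrated on the realized draws
to hit a configured Spearman correlation (default −0.4).

Because mutations are drawn from exactly the null the test assumes,
genes with δ_g = 0 form a calibration set with known uniform p-values;
planted genes have a known excess to recover. This is also the
generator's main limitation: passing calibration shows the machinery
is self-consistent, not that real cohorts satisfy the burden-null
(real data add cohort-specific calling pipelines, subclonality,
correlated mutations, and non-exponential hazards, none of which are
emulated).

## Validation studies and problem sizes

`driverdelta.validation` packages the recurring studies; the test
suite asserts on their summaries and `scripts/acceptance.py` reports
them:

- *Null calibration*: 50 pure-null SNV/SV genes, 120 + 60 samples,
  10,000 iterations; realized type-I error within 3 binomial standard
  errors of α = 0.05.
- *Enrichment recovery*: 20 replicates, one planted coding-SNV driver
  with δ spread over 0.15–0.25, 50 samples per state, 10,000
  iterations; recovery (q < 0.05) in ≥ 90% of replicates. The planted
  class is a coding SNV because its null standard deviation
  (~0.015 at these sizes) leaves wide power margins across the whole δ
  range; copy-number classes at 50 samples/state have null standard
  deviations near 0.05, where δ = 0.15 sits too close to the
  detection boundary for a stable ≥90% criterion.
- *Antisymmetry*: relabeling the states negates observed, expected,
  and adjusted Δ exactly (the same Bernoulli draws are reused, so the
  negation is bit-exact, not statistical).
- *Hazard-ratio coverage*: 100 replicates, planted HR spread over
  3.0–4.6, 400 localized samples, ~20% carriers, censoring calibrated
  to ~40% events; the 95% Wald interval covers the planted value in
  ≥ 90% of replicates.
- *Determinism*: identical configuration and seed yield byte-identical
  output tables, compared by sha256 checksums in the run manifest.

These sizes keep the full validation suite under half a minute while
holding the Monte-Carlo error of every asserted rate several-fold
smaller than its assertion margin.

## Design choices and limitations

- The combination of per-class assay masks and per-class denominators
  means a gene's classes can have disjoint assayed sample sets; the
  union prevalence then effectively concatenates per-class
  denominators and a warning is logged.
- The differential table flags (rather than drops) mutation types with
  no assayed samples in one state; flagged rows carry NaN statistics
  and are excluded from the FDR family.
- Burden-correction applies to every class through the hit-probability
  model; no mutation class falls back to an unadjusted Fisher test,
  though `two_by_two` provides the plain Fisher machinery separately.
- The pipeline recomputes nothing from raw PSA series: biochemical
  relapse and metastasis endpoints enter as labeled (time, event)
  pairs.
- Adjusted-Δ confidence intervals are reported from the
  continuity-corrected difference-of-proportions formula applied to
  the observed proportions; no interval is constructed for the
  Monte-Carlo expected Δ itself.
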