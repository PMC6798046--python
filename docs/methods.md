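# Methods

## Effect size and its variance

The per-study effect index is the difference of group means on the log2
scale (log2 fold change). Its sampling variance is the unpooled Welch form
`s²_case/n_case + s²_ctrl/n_ctrl` with (n−1) sample variances. The unpooled
form was chosen over the pooled two-sample variance because case and
control expression variances routinely differ in tumour/normal comparisons
and the weights fed into pooling should not assume equality. Missing values
are dropped per group; a group with fewer than two finite values is an
error, since its variance is undefined. Confidence intervals throughout use
the normal quantile 1.959964.

## Input normalisation

Deposited expression matrices arrive on either the linear intensity scale
or the log2 scale. The reader applies a threshold rule: if the matrix
maximum exceeds 50 the matrix is treated as linear and every value v is
replaced by log2(v+1). Log2 microarray values rarely exceed ~20 while
linear intensities are in the hundreds to tens of thousands, so the two
regimes are well separated; the +1 pseudo-count keeps zeros finite. The
rule is idempotent. Negative values combined with a linear-scale maximum
are rejected as ambiguous rather than silently transformed. No cross-sample
normalisation is applied beyond this: deposited processed matrices are
taken as already normalised.

Probe-level matrices collapse to gene level by keeping, per gene, the probe
with the highest mean expression over all samples (ties broken by
lexicographically smaller probe id) — the common convention when no
platform-specific rule is available. Gene symbols are matched
case-insensitively; synonym resolution is out of scope.

## Dataset inclusion

A study enters the compendium iff its design is case-vs-control expression
profiling by array, total n ≥ 20, each group has ≥ 5 samples, and the
organism is Homo sapiens. Decisions carry the full list of violated
criteria, never just the first.

## Pooling and model selection

Fixed-effects pooling uses inverse-variance weights 1/vᵢ; Cochran's Q is
the weighted sum of squared deviations from the fixed-effects mean, with
df = k−1. The heterogeneity fraction is I² = 100%·(Q−df)/Q, truncated at 0
when Q ≤ df (Q finite keeps I² < 100). The between-study variance uses the
DerSimonian–Laird moment estimator — the standard estimator tied directly
to Q; REML/Paule–Mandel variants are deliberately not offered. Model
selection follows the truncation: fixed effects iff I² = 0, otherwise
random effects with weights 1/(vᵢ+τ²). The pooled test is a two-sided
normal z-test, standard for inverse-variance pooling at these study counts;
no Hartung–Knapp small-sample adjustment is applied. Reported weights are
normalised to sum to 1.

Degenerate inputs: a gene measured in a single study pools trivially to
that study's effect (Q = 0, df = 0, p-Q defined as 1) and is flagged rather
than dropped. A zero sampling variance (constant expression in both groups)
would give an infinite weight; such studies receive the smallest positive
variance among the gene's studies, logged. If every study has zero
variance, pooling is refused.

## Screening

Consensus genes satisfy p < 0.01 and |pooled LFC| > 1, both strict, applied
to raw p-values — the screen is a fixed-criteria filter over a
pre-specified signature, not a genome-wide discovery scan, so no
multiple-testing correction is applied by default. A Benjamini–Hochberg
column is available for reference and never alters the screen.

## Coexpression survival

The two-gene coexpression score is the per-patient mean of the two
expression values; patients strictly above the cohort median are "high"
(score exactly at the median goes to "low", which keeps the split
deterministic for tied data). Groups are compared with the standard
two-group log-rank test (hypergeometric variance at each distinct event
time), delegated to lifelines. The hazard ratio comes from a
single-binary-covariate Cox partial likelihood with Breslow tie handling,
maximised by a bracketed root search on the score function over
β ∈ [−30, 30]; the CI and Wald p use the observed information at the
maximum. Separation (no sign change of the score) is reported as a
distinct error, not a crash. A brute-force grid search over β and a
lifelines fit serve as independent cross-checks in the tests, never as the
implementation.

## Study-covariate regression

Per-study log2 fold change (the same effect index used in pooling) is
regressed by OLS on an intercept, total sample size, country dummies
(reference level: alphabetically first country) and calendar year. Numeric
factors report coefficient t-tests with 95% CIs; the multi-level country
factor reports one joint partial F-test p-value comparing the full model
against the country-free model, so every factor yields a single p. At
least two countries are required; rank-deficient designs are rejected with
the offending columns named. A constant response uses the degenerate
convention: zero slopes, p = 1.

## Synthetic-data generator

The generator mirrors the random-effects model the analysis assumes.
Per compendium, each gene's baseline control expression is drawn once from
N(8, 2²) log2 units — the typical processed microarray range, which also
exercises the log2-detection rule (values stay below the threshold 50).
Each study's realised effect for gene g is μ_g + country shift +
N(0, τ²_g); Gaussian study effects are the standard random-effects
assumption. Samples add independent N(0, σ²) noise, σ = 1 log2 unit by
default — a typical between-sample spread for processed microarray data.
Per-study boolean gene masks emulate platform panels, so a gene can be
measured in k < K studies. Sub-seeds derive deterministically from
(seed, study index), making studies independent yet reproducible;
identical seeds and parameters give bit-identical output.

Survival cohorts draw two gene expressions around a baseline with half the
patients shifted by `median_gap` (default 2 log2 units), so the median
split recovers the intended groups; event times are exponential with
baseline hazard 0.1 per time unit, multiplied by the planted hazard ratio
in the realised high group. Censoring is administrative and independent of
group: with probability `censor_rate` a record is censored at a uniform
fraction of its event time.

What the generator does **not** emulate: probe-level artifacts (background,
saturation), platform annotation files, correlated genes, non-Gaussian
expression noise, or informative censoring. Passing tests therefore show
that the statistical machinery recovers truth under the model's own
assumptions — not that those assumptions hold in any particular public
dataset.

## Demo compendium

The demo workspace mirrors a published 13-dataset gastric-cancer
collection: the same group sizes and countries, two planted consensus genes
(CXCL8, μ = 1.64, on 10 of 13 platforms; MMP9, μ = 1.40, on 6), 102 null
genes, a +0.5 log2 country shift for one country (so the regression stage
has signal), and an n = 200 survival cohort with a planted hazard ratio of
2.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make their statistical
tolerances meaningful at interactive runtimes: 500 random instances for
oracle equivalence (1e-12), 1000 null genes for type-I calibration
(expected rate 0.01, binomial SD ≈ 0.003), 500 replicates for recovery and
coverage, 100 replicates for the end-to-end screen, 1000 replicates for
log-rank null calibration, 200 for Cox recovery and regression power. All
simulations are seeded; hypothesis-based property tests are derandomised.
The acceptance script uses 300 coverage replicates.

## Known limitations

- The z-based random-effects CI with DerSimonian–Laird τ² is known to
  undercover slightly at small k (the coverage study reports ~92–94% at
  k = 10), which is inherent to the method, not a defect of the
  implementation.
- The inclusion filter works from declared metadata; it does not verify
  group labels against the expression files.
- GEO/TCGA ingestion is out of scope: real studies enter through the
  tab-separated table reader, and the survival stage reads a pre-made
  cohort CSV.
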