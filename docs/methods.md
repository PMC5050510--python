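# Methods

## The analysis problem

Post-stress plasma cortisol in farmed fish varies enormously between
individuals, and part of that variation is a stable individual trait: some
fish mount a consistently low cortisol response (LR, the proactive coping
style) and some a consistently high one (HR, reactive).  `stressrep`
implements the statistical core of a repeated acute-stress design that asks
three questions about a cohort of fish nested within full-sib families and
stressed at several monthly occasions:

1. Is the cortisol response *repeatable* — how much of the variance is
   among-individual rather than within-individual noise?
2. Which individuals are consistent low / high responders?
3. Do the two responder types differ in their liver transcriptome —
   specifically, which transcripts are expressed exclusively in one type,
   and which GO terms are over-represented among them?

## Cortisol model and standardization

Raw cortisol differs in mean and spread between sampling occasions
(habituation, season, assay batch), so each occasion is standardized
separately:

    z_it = (x_it − mean_t) / sd_t

with the mean and sample SD (denominator N−1) taken over the fish observed
at occasion *t*.  The sample-SD convention is a package choice; any
per-occasion affine transform of the raw data leaves all downstream results
unchanged, which the test suite asserts as a property.

### Responder classification

Each fish's Z-scores are summed over its observed occasions.  A consistently
high responder accumulates a large positive sum, a consistently low
responder a large negative one, and an inconsistent fish stays near zero —
the sum captures intensity *and* consistency.  Fish are ranked by summed Z
and the lowest/highest `floor(q·N)` are labelled LR/HR (default q = 0.25,
the classical quartiles; N = 64 therefore yields 16 + 16).  Boundary
handling is not standardized anywhere, so ties are broken deterministically
by (score, fish id) and logged when they straddle a quartile boundary.
Because summed Z favours fish observed at more occasions in unbalanced
tables, a `method="mean"` variant divides by the number of observed
occasions.

## Repeatability

Repeatability is the ANOVA intraclass correlation

    r = s²_among / (s²_among + s²_within)

estimated from the mean squares of a two-level nested ANOVA (individuals
within families) by the Lessells–Boag small-sample correction:

    n0 = [Σn_i − Σn_i²/Σn_i] / (a − 1)
    s²_among  = (MS_ind − MS_within) / n0
    s²_within = MS_within

where n_i are the individuals' replicate counts and a the number of
individuals.  The sums of squares are the method-of-moments decomposition
for unbalanced data (SS_within over individuals, SS_ind over individuals
about their family means, SS_family over family means about the grand
mean); significance is F = MS_ind/MS_within on (a − f, N − a) df.

Two deliberate conventions:

* **Family is a blocking stratum.**  The default r excludes the family
  variance from the denominator, i.e. it is the within-family
  repeatability.  `include_family=True` adds the family component (via the
  EMS solution below) for a cohort-wide intraclass correlation.
* **Measurement error** is defined as sqrt(MS_within) in trait units and is
  therefore reported on the raw ng·ml⁻¹ scale even when r itself is
  computed on Z-scores; both response scales are exposed through the
  `response` switch.

A negative s²_among (MS_ind < MS_within) is reported as a negative r with a
flag, never silently clamped.

### Variance components

The three components (family, individual-within-family, residual) are
solved from the expected mean squares of the unbalanced nested design
(Searle-type coefficients; they reduce to n, n, n·m in the balanced case),
bottom-up from MS_within.  This is the closed-form moments solution, chosen
over REML because it is exactly testable against brute-force sums of
squares; negative solutions are reported raw and truncated to zero for the
percentage decomposition, with a flag.  Simulation tests recover planted
components to within 10% relative at a 30-family × 20-fish design.

### Group statistics

Group comparisons of resting, total and free cortisol use the classical
pooled-variance two-sample t (df = n₁ + n₂ − 2), computable from raw values
or from published mean/SD/n summaries — the two routes agree to floating
tolerance by construction.  The percentage of free (protein-unbound)
cortisol is 100·free/total per fish, with zero totals and free > total
flagged rather than silently handled.  The LR-vs-HR time-course comparison
is a split-plot (mixed) ANOVA — responder group between subjects, sampling
occasion within — delegated to `pingouin.mixed_anova` and cross-checked in
the tests against hand-computed balanced split-plot sums of squares.
Normality (Lilliefors-corrected KS against a fitted normal) and variance
homogeneity (Levene, mean-centered) are computed as report-only
diagnostics; they never gate an analysis.

## Transcriptome screen

Libraries are normalized with median-of-ratios size factors (median over
all-positive transcripts of count/geometric-mean, rescaled to geometric
mean 1).  Transcripts with total count below `min_total` (default 10; the
threshold is design-free and configurable) are dropped first.

### Negative-binomial pairwise test

Counts are modelled NB with Var = μ + α·μ².  A single pooled dispersion α
is estimated by a global method of moments — pooled within-group variances
regressed against squared means across all transcripts with normalized mean
≥ 1, floored at 10⁻⁸ — because per-transcript estimates are hopeless at
three replicates per group.  Each transcript is then tested with an exact
conditional test: given the total count K = K₁ + K₂, the conditional
distribution of the group-1 sum under equal normalized means is the
normalized product of the two group-sum NB pmfs (moment-matched to the
size-factor sums), and the two-sided p is the total probability of outcomes
no more likely than the one observed.  Totals above 20 000 switch to a Wald
normal approximation on the normalized group means.  All-zero transcripts
get p = 1 by convention.  Null simulations at 3 + 3 replicates put the
empirical type-I rate within binomial error of the nominal 0.05 across
dispersions 0–0.5.  This test is a transparent simplification of the
classic DESeq pairwise test; it approximates, and does not attempt to
reproduce, that tool's output.

### Exclusivity filter

A transcript is called exclusive to a group iff every replicate of that
group has a count ≥ `detection_min` (default 1), every replicate of the
other group has a count ≤ `absence_max` (default 0), its raw p < α and its
Benjamini–Hochberg q < the FDR threshold (both default 0.05, adjusted
across all tested transcripts).  "Detected/absent" thresholds are
configurable because presence/absence is not well-defined at the count
level without them.

### Enrichment and clustering

GO-term enrichment of an exclusive gene set uses Fisher's exact test on the
2×2 table (study∩term, study∖term; rest∩term, rest∖term) over a background
universe of all transcripts surviving the low-support filter — standard
enrichment practice, configurable.  The default is the two-sided test with
BH correction across terms; a one-sided over-representation alternative is
exposed.  The heatmap view standardizes each transcript across samples
(relative expression), clusters rows and columns with average-linkage
Euclidean hierarchical clustering, and reports whether the top-level column
split separates the two responder groups perfectly (purity 1).

## Synthetic data

The generators define the study conditions under which everything is
tested; all draw from a single seeded PCG64 engine per call, so identical
configs give byte-identical outputs.

* **Cortisol** — additive random-effects model
  `x = m_t + s_t·(F_f + I_i + e)` with family, individual and residual
  components, occasion-specific location m_t and scale s_t, record-wise
  MCAR missingness, and negative draws floored at 0 (flagged; the analysis
  operates on ranks and Z-scores, so rare floors are immaterial).  Defaults:
  6 families × 12 fish × 4 occasions; occasion means around 300 ng·ml⁻¹
  with SDs near 87 ng·ml⁻¹ — the scale of post-stress plasma cortisol in
  European sea bass, a notoriously high-cortisol species; variance split
  (2500, 3000, 4500) ng²·ml⁻², i.e. a true within-family repeatability of
  0.4 and a 25% family share; missing rate 0.2, mirroring the unbalance of
  real repeated samplings.
* **Counts** — NB counts at baseline mean 100 and dispersion 0.1 for
  2000 transcripts × (3 + 3) samples, with 169 LR-exclusive and 161
  HR-exclusive transcripts planted (zero in the other group, at least one
  count in every own-group replicate).
* **Annotation** — terms draw ~Poisson(20) member genes; planted enriched
  terms over-sample a designated study set by a configurable fold.

What the generator does **not** emulate: assay floor/ceiling censoring,
non-normal cortisol distributions, informative missingness, correlated
library-preparation effects, transcript-length biases, or the dependence
structure of a real de-novo transcriptome.  Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to every artefact of real data.

## Numerical and design notes

* The F test for repeatability applied to Z-scored data is mildly liberal
  (empirical type-I ≈ 0.06 at nominal 0.05 in the default design): the
  per-occasion standardization estimates a mean and SD per occasion, which
  the nested-ANOVA degrees of freedom do not discount.  The effect
  disappears on the raw scale with homogeneous occasions.
* Quartile sizes use floor(q·N); ties at the boundary are resolved by
  fish id and logged.
* The published free-cortisol group tables this design echoes report a
  subsample of n = 10 per group alongside t statistics with df = 8; the
  pooled t reproduces the printed total-F and %Free statistics exactly with
  n = 5 per group, and the free-F statistic with neither n.  The package
  implements the standard pooled t and documents, rather than
  reverse-engineers, the discrepancy.
* Exact reproduction of a published exclusive-transcript count is out of
  reach without the original assembly and quantification; the screen is
  validated by planted-truth recovery and brute-force rule scans instead.
* Problem sizes used by the reproduction script: 500 simulated cohorts for
  the repeatability recovery, 1000 for the null rejection rate, one
  2000-transcript matrix for the screen — sizes at which the Monte-Carlo
  error of every reported quantity is well below its acceptance band.

## Limitations

No REML/Bayesian repeatability with confidence intervals (rptR-style); no
heritability or QTL analysis; no read-level processing (QC, assembly,
quantification, annotation retrieval) — the pipeline starts from a count
matrix; plots are emitted as plot-ready tables, not figures.
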