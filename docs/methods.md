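# Methods

## The problem

High-content imaging turns each cell population (a wild-type replicate
culture or a gene-deletion mutant) into hundreds of quantitative
morphological features: lengths and areas (non-negative continuous),
bounded ratios, within-sample noise measures (real-valued), cell-type
proportions (count pairs), and unbounded counts.  Detecting subtle mutant
phenotypes parametrically requires, per feature, a probability model whose
family actually fits and whose wild-type distribution is unimodal — batch
structure, contaminating subpopulations and outliers all masquerade as
extra modes.  This package implements the full chain: data-type-aware
family selection, mixture-based modality testing with confounder/outlier
rescue, Wald-style mutant scoring with q-value FDR, and a canonical-
correlation layer linking morphology to gene-function annotations.

## Family catalogue and selection

Candidate families by data type:

| type | candidates |
|---|---|
| NONNEG | gamma, Weibull, log-normal, inverse Gaussian, exponential |
| RATIO | beta, logit-normal |
| REAL | Gaussian (via normality gate), logistic, reverse Gumbel |
| PROPORTION | binomial, beta-binomial |
| COUNT | Poisson, negative binomial |

The reverse Gumbel is the minimum-type (left-skewed) extreme-value
distribution, i.e. the mirror of the classical maximum form; we use the
location–scale parameterization.  Beta-binomial uses (mean `p`,
intra-class correlation `rho`), variance `n p (1-p) (1 + (n-1) rho)`.

REAL features pass through a Shapiro–Wilk gate first: the raw P value is
Bonferroni-multiplied by the number of REAL features in the run, and the
feature is declared Gaussian when normality is **not** rejected at
alpha = 0.05.  Only gate failures enter the AIC race over the remaining
real-support candidates.  All other types race all candidates by AIC
(`-2l + 2k`), ties broken by fewer parameters, then candidate order; the
full AIC table is retained.

Fitting is maximum likelihood throughout.  Families with closed-form or
1–2-dimensional Newton solutions (Gaussian, log-normal, logit-normal,
exponential, inverse Gaussian, Poisson, binomial, gamma, Weibull,
logistic, reverse Gumbel, beta, beta-binomial) use those deterministic
solvers; anything else falls back to BFGS on link-transformed parameters
from method-of-moments starts.  All solvers accept observation weights —
this is what the mixture EM M-steps consume.  Standard errors come from
closed forms where exact, otherwise from a central-difference Hessian of
the log-likelihood.  Ratio observations exactly at 0 or 1 are shrunk by
`(y (n-1) + 0.5) / n` before beta/logit-normal fitting, since the
likelihood is unbounded at the boundary.

## Modality

A feature is unimodal when mixture-model clustering under its assigned
family selects one component.  For c = 1..c_max (default 10, subject to
n >= 3c) a c-component mixture is fitted by EM: restart 0 initializes
responsibilities from a quantile-sliced partition, further restarts from
random Dirichlet responsibilities; a component whose weight drops below
1/n aborts the run (collapse).  The best restart's BIC
(`-2l + k ln n`, k = c·k_family + c - 1) enters a per-repetition minimum;
the final c* is a majority vote over `n_randomizations` repetitions with
distinct restart seed streams, ties to the smaller c.

Features that look multimodal get two rescue stages:

1. **Confounder adjustment.** All confounder factors are combined into one
   categorical factor (a one-way layout, so factor interactions are
   implicit in the level combinations).  Per level, the family's location
   is refitted with the dispersion held at the grand fit; effects are the
   level locations minus their sample-weighted mean on the canonical link
   scale (sum-to-zero parameterization, which keeps the grand location
   where the data put it even when the family is misassigned on the raw
   mixture).  Continuous observations are shifted by minus their level
   effect on the link scale; counts are mapped through mid-CDF quantile
   residuals from the level fit back through the grand fit.  Levels with a
   single sample keep a zero effect (warned).
2. **One-percentile outlier trimming.** Under the single-component fit of
   the adjusted data, observations with two-sided tail mass below 0.01
   (CDF < 0.005 or > 0.995; for discrete data the lower tail uses
   F(y-1)) are removed, hardest-to-explain first, capped at 2% of the
   sample.

The verdict of every stage is recorded; a feature is finally unimodal iff
some stage selects c = 1.  Residual multimodality is only flagged — it may
reflect unknown confounders or genuine biology.

## Mutant scoring

The null model of a feature is the family MLE on the modality-processed
wild-type replicates (default 114).  When a feature resolved at a rescue
stage, the pipeline re-selects the family on the processed data before
fitting the null: the raw-stage assignment described the confounded
mixture, not the distribution mutants are compared against.

Per mutant observation y:

* `P = 2 min(F0(y), 1 - F0(y))` (continuous) or
  `2 min(F0(y), 1 - F0(y-1))` (discrete), capped at 1 — exactly uniform
  under a continuous null.
* `Z = (b_j - b_0) / SE`, with `b_j` the location MLE refit to the
  mutant's observation(s), dispersion fixed at the null, and `SE` from the
  expected Fisher information of the location **evaluated at the null
  parameters**.  Evaluating the information at the null rather than at the
  one-observation refit is deliberate: for mean-parameterized families
  (Gaussian, gamma) it makes Z exactly centred with unit variance under
  the null, whereas information-at-the-estimate Wald values from a single
  observation are noticeably biased for log-link families.  Logit-normal
  features are scored on the logit scale, where the model is exactly
  Gaussian.  Beta-binomial rule: a mutant numerator equal to the
  wild-type-estimated value `p0 * n` gives Z = 0 exactly; any non-finite
  Wald value is capped at the maximum finite |Z| of the other mutants with
  matching sign (with null-evaluated information this cap is a safety net,
  not a code path that triggers in practice).

q-values follow Storey: `pi0(lambda) = #{p > lambda} / (m (1 - lambda))`
on lambda = 0.05..0.95 (step 0.05), a cubic-polynomial smoother evaluated
at lambda = 0.95, clipped to (0, 1] (pi0 = 1 below m = 20); then the usual
step-down minimum.  Forcing pi0 = 1 reproduces Benjamini–Hochberg exactly.
q-values are estimated per feature across the mutant panel (a pooled mode
exists); a (mutant, feature) pair is significant at q <= FDR (default
0.01) and a mutant is abnormal iff significant in at least one feature.

## Morphology–function network

The annotation matrix (genes x terms, Boolean) keeps terms annotating
3..199 genes, collapses duplicate columns, and drops unannotated genes.
Both data sides are reduced by column-centered PCA to the smallest
component count whose cumulative contribution ratio reaches the threshold
(phenotype 0.95, function 0.99).  CCA is computed by SVD of the whitened
cross-covariance (ridge 1e-8 on the covariance eigenvalues);
Bartlett's sequential statistic
`-(n - 1 - (p+q+1)/2) sum_{i>k} ln(1 - rho_i^2)` with `(p-k)(q-k)` df
selects the number of significant canonical pairs at alpha = 0.05.

Gene groups come from complete-linkage hierarchical clustering on the
binary (Jaccard) distance between annotation vectors, cut just below
height 1; singletons are dropped.  Each group's terms are tested by
two-sided Fisher's exact test against the annotated universe, Bonferroni
over all (group, term) pairs at alpha = 0.05; the lowest-P enriched term
is the representative.  Every unordered group pair is tested by a CCA in
which the observations are the pCV dimensions and the variables the
member genes' pCV profiles; a side with at least half as many genes as
pCV dimensions is PCA-compressed to `(n_pcv - 1) // 2` components so the
Bartlett factor `n - 1 - (p+q+1)/2` stays positive (with 32 pCVs and up
to 31 variables per side it would go negative and the test would be
meaningless).  The first dimension's Bartlett P, Bonferroni-multiplied by
the number of pairs, is compared to alpha = 0.0005.

The network keeps all within-group gene–gene Pearson correlations of pCV
score vectors; a cross-group edge exists only for significant group pairs
and only for the gene pair with the maximum |r| of that group pair (the
per-group-pair reading of the zero-filling rule; a per-gene reading is
also defensible).  Coordinates come from a seeded Fruchterman–Reingold
layout weighted by |r| — dense-group calls therefore depend on the layout
seed, which is a recorded configuration value.  Core groups are the
higher-mean cluster of a two-component Poisson mixture on group degrees
(number of significant partner groups); dense groups the lower-mean
cluster of a two-component gamma mixture on mean within-group embedding
distances.  These boundaries are data-derived, not fixed constants; the
implied cutoffs are reported.  The two-component splits use a dedicated
1-d EM refined from every sorted-split initialization (effectively
exhaustive), because group counts can be far below what the general
mixture machinery requires.

## Synthetic data

The generator defines the study conditions: 114 wild-type replicates, a
5-level combined confounder factor assigned cyclically, one feature per
data type with field-plausible parameters (gamma(4, 2) cell size,
Weibull(3, 1.5) neck width, beta(8, 4) axis ratio, N(0, 1) noise,
beta-binomial(0.35, 0.02) budded fraction with 200 cells per sample,
Poisson(3) counts), one Gaussian feature with centred two-sided batch
shifts of ±3 sd (6 sd between batches; centred so the adjusted wild-type
location matches the batch-free mutant draws), and one Gaussian feature
with 2% contamination at 8 sd.  Mutant panels default to 1000 mutants
(200 in the bundled demo), one observation per (mutant, feature); planted
effects are link-scale location shifts measured in units of the feature's
link-scale spread, so log- and logit-link features receive shifts
comparable to identity-link ones.  A master seed expands into per-feature
substreams via `SeedSequence(master, spawn_key=(tag, index))`, so adding a
feature never perturbs the draws of another.  The annotation generator
partitions genes into groups owning disjoint term blocks with a hub term
per group (within-group binary distance < 1, cross-group distance exactly
1) and couples phenotype scores to group latents with strength
`coupling`.

What the generator does **not** emulate: the covariance structure of real
morphological parameters (features are independent given the design),
the heavy-tailed measurement error of real imaging, realistic annotation
overlap between functional groups, and any dataset-specific counts.
Passing tests therefore demonstrate correctness and calibration of the
machinery under its stated model, not performance on any real screen.

## Numerical choices and problem sizes

* EM: relative log-likelihood tolerance 1e-8, max 500 iterations, 10
  restarts and 10 randomizations by default.  Simulation studies and the
  bundled pipeline run at desk scale: c_max 4–5, 3 restarts, 3
  randomizations, tolerance 1e-6, max 200 iterations — chosen once as the
  package's standard small-study settings.
* The acceptance script reports rates over 30–50 replicates (1000 for the
  Bartlett null study); the criterion-level tests in the suite use the
  full 100/1000-replicate designs.
* Optimizer convergence is declared at BFGS success or a finite-difference
  gradient norm below 1e-4 · max(|nll|, 1); non-convergence is reported in
  the `FitResult`, never silently accepted.
* Ties in AIC go to fewer parameters, then candidate order; ties in the
  component vote to smaller c.
* Degenerate inputs: constant data refuse a Gaussian/scale fit; a
  confounder level with one sample keeps a zero effect; all-equal degrees
  or distances yield no core/dense flags (warned).

## Known limitations

* The mutant Wald Z for a single observation relies on the null-evaluated
  expected information; with mutant replicates a joint location refit is
  used, but dispersion is never re-estimated per mutant.
* The confounder model is strictly one-way; a factor whose effect varies
  with another factor beyond their level combinations is out of scope.
* The LOESS smoother implements the classical tricube local polynomial
  without robustness iterations.
* Mixture BIC is the only modality criterion (no dip-type tests), so
  heavy-tailed unimodal families can occasionally read as c = 2 at small
  n; the randomization vote mitigates but does not eliminate this.
* No zero- or one-inflated family variants are provided.
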