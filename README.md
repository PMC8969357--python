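# unimo

Parametric statistics for quantitative morphological phenotyping.

High-content imaging pipelines (CalMorph for budding yeast, CellProfiler
and kin elsewhere) reduce each sample — a wild-type replicate culture or a
gene-deletion mutant — to hundreds of numeric morphological features.
`unimo` models each feature with an explicitly chosen unimodal probability
distribution and uses the fitted wild-type null for mutant calling and
network analysis, instead of transforming everything toward normality or
falling back to non-parametric tests.

The pipeline, per feature:

1. **Data type** — non-negative continuous, bounded ratio, real-valued
   noise, proportion count pair (k successes of n cells), or count.
2. **Family selection** — candidate families per type (gamma, Weibull,
   log-normal, inverse Gaussian, exponential / beta, logit-normal /
   Gaussian, logistic, reverse Gumbel / binomial, beta-binomial / Poisson,
   negative binomial), chosen by AIC; real-valued features first pass a
   Bonferroni-corrected Shapiro–Wilk gate that assigns the Gaussian
   whenever normality is not rejected.
3. **Modality** — finite mixtures of the assigned family with c = 1..10
   components, c chosen by BIC with a randomized-restart majority vote;
   apparently multimodal features are rescued by a one-way GLM of the
   confounder levels (effects removed on the link scale) and, failing
   that, by one-percentile outlier trimming (two-sided tail mass < 0.01,
   at most 2% of points).
4. **Mutant calling** — two-tailed tail probability under the wild-type
   null, Wald Z = (b_mutant − b_null)/SE, and Storey q-values; a mutant is
   morphologically abnormal if q ≤ FDR (default 0.01) in at least one
   feature.
5. **Morphology–function network** — a filtered Boolean gene×term
   annotation matrix and the mutant Z matrix are PCA-reduced (95% / 99%
   cumulative contribution) and linked by canonical correlation analysis
   with Bartlett's sequential test; genes cluster into functional groups
   (complete linkage on binary distance), group pairs are tested by CCA of
   their pCV profiles (P < 0.0005 after Bonferroni), and the resulting
   correlation network is classified into core (high-degree, Poisson
   mixture split) and dense (compact, gamma mixture split) groups.

A synthetic-data module generates wild-type panels (114 replicates, all
data types, batch structure, contamination, outliers), mutant panels with
planted link-scale effects, and coupled annotation/phenotype data — so the
whole pipeline is testable without any external dataset.

## Worked example

Run the bundled synthetic study end to end (114 wild-type replicates, 200
mutants, 10 planted effects, a 5-level confounder, one feature with a 6 sd
batch split and one with 2% outlier contamination):

```
$ unimo all --seed 7 --out demo_out
[simulate] wt_values=wt_values.tsv, mut_values=mut_values.tsv, n_planted_effects=10
[assign] n_features_assigned=8
[modality] n_unimodal=8, n_features=8
[test] n_features_tested=8, n_abnormal=7, n_mutants=200
[network] n_groups=6, n_pairs_tested=15, n_significant_pairs=0, n_canonical_pairs=0
```

Reading the output: all 8 features end up with a unimodal model — 7 at the
raw stage and the batch-split feature only after confounder adjustment
(see `demo_out/modality.tsv`).  7 of the 200 mutants are called abnormal
at FDR 0.01; all 7 carry planted effects and no null mutant is flagged —
see `demo_out/test_summary.tsv` against `demo_out/ground_truth.json` (two
of the three misses are proportion-type effects, where a single (k, n)
observation carries less information).  The network stage finds no significant
group pairs because the demo's annotations are uncoupled from the
phenotypes: at P < 0.0005 after Bonferroni that is the correct null
answer.

Every stage writes plain TSV/JSON artifacts (`assignments.tsv`,
`modality.tsv`, `test_results.tsv`, `z_matrix.tsv`, `groups.tsv`,
`edges.tsv`, a manifest with the config hash and seed), and the same
config + seed reproduces them byte for byte.  Library use mirrors the
CLI:

```python
from unimo import select_family, assess_modality, fit_null, mutant_test
from unimo.feature_model import DataType

assignment = select_family(values, DataType.NONNEG)      # AIC race
report = assess_modality(values, assignment, levels=batches)
null = fit_null(report.processed_data, assignment.family)
P, Z = mutant_test(observation, null)
```

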