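# Methods

`rhizotype` implements a complete two-group microbiome discrimination
workflow of the kind used to type crop cultivars by their rhizosphere
bacterial communities: diversity profiling, unsupervised grouping, O-PLS-DA
screening, multi-classifier validation with importance-intersection feature
selection, and a taxa → nutrients → quality path analysis.  This note
documents the models, the defaults and why they were chosen, the synthetic
data generator's assumptions, and the numerical choices that matter.

## Data model

The canonical container is a taxa × samples matrix (`AbundanceTable`) tagged
as raw read `counts` or `relative` abundances (columns summing to 1).
Sample metadata carries an optional group label ("A"/"B"), soil available
N/P/K and leaf polyphenols/theanine/caffeine, all in mg/kg.  Dominance
("genera above 1 %") is computed on the *mean of per-sample relative
abundances*, so unequal sequencing depths do not weight deeply sequenced
samples more heavily.

## Synthetic data generator

The generator emulates a 44-cultivar rhizosphere 16S study: two groups of
31 and 13 samples, 745 genera, 23 planted "characteristic" genera (19
enriched in group A, 4 in group B) shifted by a factor of
2^1.6 ≈ 3 between the group base profiles.

* **Counts** are Dirichlet-multinomial: per sample,
  p ~ Dirichlet(α · profile_group), counts ~ Multinomial(depth, p), with
  depth ~ Poisson(50 000).  A single concentration scalar α controls
  biological overdispersion on top of multinomial noise.  The default
  α = 5000 was fixed so that the generator reproduces the statistical
  regime the workflow is designed for: a clean unsupervised two-group
  split, a cross-validated O-PLS-DA Q² around 0.73, and roughly 150–200 of
  745 genera passing VIP > 1.  Smaller α (500–2000) produces communities
  whose group structure is invisible to K-means in the full feature space —
  a different, harder regime than the one this workflow addresses.
* **Background profile** follows a power law (rank^−0.9), giving the steep
  rank-abundance curve typical of soil communities.  Characteristic taxa
  occupy moderately abundant ranks (10–250) so that they are detectable but
  do not dominate the community.
* **Phenotypes are chained, not parallel.**  A latent *taxon load* per
  sample is the direction-signed average of z-scored characteristic-taxon
  abundances.  Nutrients are linear in `path_strength · load` plus Gaussian
  noise; quality traits are the same construction applied to a latent
  *nutrient load*, never to the taxa directly.  Group differences in
  chemistry therefore arise only through the taxa, which makes path-model
  recovery a genuine test: at `path_strength = 0` the chemistry decouples
  from the community entirely.  The linear maps are anchored so that at
  full path strength the group means sit on the midpoints of the per-group
  reference ranges (e.g. available N ≈ 63 mg/kg in A vs ≈ 30 mg/kg in B);
  the noise scale is half the average half-width of those ranges, so
  simulated values span the reference windows approximately rather than
  exactly.

What the generator does **not** model: replicate nesting within cultivars
(samples are exchangeable), taxonomic correlation structure (genera are
independent given the profile), read-level artifacts (chimeras, depth-quality
interactions), and zero-inflation beyond what the Dirichlet-multinomial
produces.  Passing recovery tests therefore show that the chain of methods
is implemented correctly and is sensitive at realistic effect sizes — not
that it would perform identically on real soil communities.

## Diversity

Shannon uses the natural log (a `base` argument provides the log2 variant);
Simpson is reported as Gini–Simpson (1 − Σp²); Chao1 is
S_obs + F1²/(2·F2), falling back to the bias-corrected
S_obs + F1(F1−1)/2 only when no doubletons exist.  Rarefaction is the
analytic hypergeometric expectation
E[S(d)] = Σ_i [1 − C(N−N_i, d)/C(N, d)] evaluated with log-gamma
differences (no Monte Carlo, stable for N in the millions).  Bray–Curtis is
computed on relative abundances by default so that depth differences do not
masquerade as community turnover.

## Grouping and group tests

K-means (Lloyd, k-means++ init, 25 restarts) runs on z-scored features so
abundant genera do not dominate the Euclidean geometry; `k="auto"` scans
k = 2..8 and keeps the best mean silhouette.  Group comparisons default to
Welch's t-test with Benjamini–Hochberg adjustment across the feature batch;
a group with zero variance triggers an automatic Mann–Whitney fallback.
Mann–Whitney uses the exact null distribution when both groups have ≤ 8
samples and the tie-corrected normal approximation otherwise.

## O-PLS-DA

The model autoscales X (unit variance — the standard choice for
compositional omics tables; Pareto is available), codes the two classes
±1, and iteratively strips label-orthogonal components (Trygg–Wold) before
fitting one predictive NIPALS component.  Key quantities:

* **R²Y** = 1 − RSS/TSS on the training labels.
* **Q²** = 1 − PRESS/TSS by 7-fold venetian-blind cross-validation (folds by
  sample index modulo 7, so a group-sorted table distributes both classes to
  every fold).
* **n_ortho="auto"** adds orthogonal components while CV Q² improves by more
  than 0.01 (max 5); with nothing to strip the model reduces exactly to
  PLS-DA.
* **VIP** is computed on the predictive component only, which collapses to
  √p·|w_j|/‖w‖ and satisfies mean(VIP²) = 1 identically — the screening
  threshold VIP > 1 then has the usual "above-average influence" reading.
* The **permutation test** refits the model under label permutation and uses
  the add-one estimator p = (#{perm ≥ obs}+1)/(n_perm+1), so p can never be
  0 and the attainable minimum at 200 permutations is 1/201 ≈ 0.005.
* The **S-plot** reports p1 (covariance of the scaled variable with the
  predictive score: magnitude) against p(corr) (correlation: reliability);
  zero-variance variables are flagged and excluded from screening.

## Validation harness

Five classifier families — KNN, RBF-SVM, a single-hidden-layer
backpropagation network (logistic activations, L2 decay, LBFGS), random
forest (500 trees), and gradient boosting (XGBoost, exact splits) — are run
through repeated stratified 80/20 holdout.  Each iteration tunes every
family by stratified 5-fold grid search on the training split (accuracy
criterion), refits the winner, and records held-out predictions and class-1
scores; iteration i uses seed master+i, so runs are exactly reproducible.
Results are *pooled*: confusion counts summed over iterations, one ROC per
family from the concatenated score/label pairs, AUC by the mid-rank
Mann–Whitney formulation (ties count ½).  The SVM contributes its signed
margin through a logistic link so its scores pool on the same [0, 1] scale
as the probabilistic families.  XGBoost uses exact greedy splits: with
histogram binning the threshold can land exactly on a training class
minimum and misclassify hard-margin boundary samples, which matters at
these sample sizes.

Default tuning grids: k = 1..20 for KNN; C and σ over 10⁻³..10³ by decade
for the SVM (γ = 1/(2σ²)); hidden units {2,4,8,16} × decay {0, 0.01, 0.1};
a four-point mtry grid {1, √p, p/3, min(59, p)} for the forest (the full
1..min(59, p) scan is available via `full_rf_grid` but costs ~15× more); a
64-combination XGBoost grid over n_estimators/depth/learning-rate/
subsampling.  `HarnessConfig.fast()` thins these grids and defaults to 10
iterations — the preset used by the pipeline driver and the bundled
analysis scripts, sized so a full run stays in the minutes range on one
core.  Feature importance is a full-data fit (impurity for the forest,
total gain for boosting), and the characteristic set is the intersection of
the two top-30 rankings, ordered by summed rank.

## Downstream analyses

* **RDA** standardizes responses and constraints (correlation RDA — taxa
  and chemistry live on different scales), regresses Y on X by rank-reduced
  least squares, and eigen-decomposes fitted and residual covariances
  separately; the constrained proportion is Σλ_constrained / total variance.
* **Correlation networks** keep edges with |r| ≥ 0.6 and BH-adjusted
  p ≤ 0.05 (both configurable); p-values come from the t transform of r.
* **PLS-SEM** is Lohmöller's PLS-PM with mode-A (correlation) outer weights
  and the centroid inner scheme, iterated to Δw < 10⁻⁶ (max 300 iterations,
  error with trace on failure).  Latent orientation is fixed by requiring a
  positive outer-weight sum, which makes single-indicator latents equal the
  standardized indicator exactly.  Path coefficients are OLS of each
  endogenous latent on its predecessors; significance is bootstrap (500
  resamples of samples) with normal-approximation p-values.  Degenerate
  bootstrap resamples (zero-variance indicator draws) are skipped and
  counted.

## Numerical and degenerate-input conventions

Zero-variance variables: dropped with a warning in O-PLS-DA (VIP = NaN,
excluded from screening), excluded and logged in networks, an error inside
PLS-PM blocks.  All-zero samples are hard errors naming the sample.  Ties in
rank-abundance keep the input taxon order (stable sort).  Permutation and
bootstrap p-values never return exactly 0 where an add-one estimator is
defined (the bootstrap normal approximation can underflow to 0 for
overwhelming effects).  Every stochastic routine takes an explicit seed and
derives per-iteration seeds additively.

## Problem sizes used by the bundled checks

The test suite and `scripts/acceptance.py` run the full design (44 samples,
745 genera) for recovery checks, 10 replicate seeds for the
pipeline-recovery medians, 200 null datasets (24 samples × 15 variables,
99 permutations each) for permutation-p calibration, 25 harness iterations
for validation summaries, and 500 bootstrap resamples for path-model
significance.  These sizes were chosen to keep a complete run in the
minutes range on a single core while leaving the statistical conclusions
stable across seeds.

## Known limitations

Two-class discrimination only (no multi-class O-PLS-DA); no phylogenetic
diversity (requires a tree); RDA reports scores and proportions but no
axis-permutation tests; PLS-PM implements mode A/centroid only — the
settings appropriate for reflective single-block chains like
taxa → nutrients → quality.
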