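# Methods

## Overview

`shapstrat` stratifies an immunotherapy cohort by clustering patients in the
space of per-patient model attributions rather than raw expression. The
premise: a classifier trained to separate responders from non-responders
concentrates on response-relevant transcriptional programs, so the SHAP
attribution profile of each patient is a denoised, response-oriented summary
of their expression, and clusters in that space correspond to
clinically distinct subgroups even when they share a response label.

## Differential expression

Expression is analysed on the log2-TPM scale (log2(TPM + 1); the pseudocount
is configurable). For each gene a two-group model (intercept + responder
indicator) gives the log2 fold change, the pooled within-group variance
s²_g, and residual df d_g = N − 2. Variances are shrunk by the standard
empirical-Bayes hierarchy: the prior (d₀, s₀²) is estimated by moment
matching on z = log s²_g using digamma/trigamma inversion (Newton iteration
for the trigamma inverse), with d₀ = ∞ (and s₀² the arithmetic mean of the
variances) when the spread of z does not exceed chi-square sampling noise.
The moderated statistic

    t̃_g = logFC_g / (s̃_g √(1/n₀ + 1/n₁)),   s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

is referred to a t distribution on d₀ + d_g df (the normal tail when
d₀ = ∞). With d₀ = 0 this is exactly the classical pooled two-sample t. The
implementation agrees with Bioconductor limma to ~1e-14 on t, p and FDR for
finite d₀; with d₀ = ∞, limma additionally caps the total df at the pooled
df G·d_g, so p-values differ in the fourth decimal there — the formula above
is kept as stated. Zero-variance genes are flagged, excluded from prior
estimation, and retained with p = 0. DEG gates: FDR < 0.05 and linear fold
change > 1.3 (|log2FC| > log2 1.3), two-sided. No low-expression pre-filter
is applied.

## Response classifier

A binary XGBoost model (logistic objective, `tree_method=hist`, one thread
for determinism) is trained on the full cohort with the DEG features.
Defaults: `max_depth=3`, `learning_rate=0.1`, `n_rounds=200`,
`subsample=0.8`, `colsample_bytree=0.8`, `min_child_weight=10`. The last
deserves explanation: because response labels are noisy given expression
(identical transcriptional profiles can respond differently), an
unconstrained booster will memorize individual labels through splits that
isolate a handful of samples. Those memorization splits inject label noise
into every patient's attribution profile and drown the gene-program
structure the clustering is after. Requiring ≥ 10 hessian mass per leaf
(≈ 40 samples near p = 0.5) forbids such splits while leaving broad-pattern
splits untouched. All parameters are exposed in the run configuration.

## SHAP attribution matrix

Attributions use the path-dependent ("tree_path_dependent") TreeSHAP value
function: for a feature subset S, the value of a tree at x is its
conditional expectation obtained by following x's branch at splits on
features in S and averaging children by their training cover (hessian mass)
otherwise. Per tree, subset values are enumerated over the tree's own split
features (≤ 2^7 subsets at depth 3) and combined with Shapley weights;
features a tree never splits on are null players, so summing per-tree values
gives the exact Shapley value of the full model under this value function.
Everything is accumulated in float64, so local accuracy
(base + Σ_j φ_ij = margin_i) holds to ~1e-6 (the residual is xgboost's own
float32 margin), and single-tree attributions match an independent 2^M
brute-force enumeration to ~1e-15. Attributions are on the margin
(log-odds) scale; the interventional SHAP variant would differ and is not
implemented. The per-cohort base value is stored but not used for
clustering (it is sample-constant).

## Clustering in SHAP space

- **PCA.** Columns of the attribution matrix are centered and, in the
  pipeline default, scaled to unit variance before the SVD
  (correlation-mode PCA). Scaling matters: a gene's attribution magnitude
  is proportional to its effect on the margin, so without it a few strong
  genes plus the residual label-noise direction dominate the leading
  components, and weak-but-consistent co-varying programs (the axis that
  separates response-similar subclasses) fall below the retained-variance
  cut. `pca_reduce` itself defaults to centering only; the pipeline turns
  scaling on (`cluster.scale`). Components are retained up to 80%
  cumulative explained variance with a floor of two; component signs are
  fixed deterministically (largest-magnitude loading positive).
- **SNN graph.** k-nearest neighbours by Euclidean distance in the
  embedding, k = clamp(round(0.05·N), 5, min(50, N−1)), ties broken by
  sample index. Similarity = shared-neighbour count; diagonal k by
  convention (excluded when building the Laplacian).
- **Spectral partition.** Symmetric normalized Laplacian
  L = I − D^{−1/2} S D^{−1/2}; the bottom-k eigenvectors are row-normalized
  and partitioned by k-means (10 restarts, seeded). Labels are renumbered
  1..k by descending cluster size. Vertices with zero SNN degree become
  singleton clusters with a warning. The cluster count defaults to the
  eigengap (largest gap in ascending eigenvalues over k ∈ [2, 10]); a
  degenerate spectrum (gap ≤ 1e-8) falls back to k = 2 with a warning.
- **Refinement.** Sub-clustering re-runs dynamic-k → kNN → SNN → spectral
  on the target cluster's rows of the *same* embedding, extending those
  samples' hierarchy paths (e.g. `2-1`). Targets can be listed explicitly;
  the automatic rule refines the most dispersed cluster (largest mean
  distance to its embedding centroid) into two when the eigengap chose
  three top-level clusters — a programmatic stand-in for refining the
  visibly heterogeneous middle cluster.
- **Baselines.** Pearson-distance (1 − r) complete-linkage hierarchical
  clustering and seeded k-means on expression profiles.

## Stability protocol

Ten subsamples of ⌊0.9·N⌋ patients are drawn without replacement (replicate
r uses base seed + r; the pipeline inside each replicate keeps the base
seed, so a fraction-1.0 replicate reproduces the reference exactly). By
default each replicate re-runs the whole pipeline — retraining the
classifier and recomputing SHAP — with the cluster count and refinement
targets fixed to the reference's so that matching is well-posed; a cheaper
`embed` mode re-clusters the reference SHAP rows instead. Replicate labels
are matched one-to-one to reference labels by Hungarian assignment on the
shared-sample contingency table; agreement is the adjusted Rand index on
shared samples, and per-cluster CR/PR/SD/PD proportions are averaged across
replicates (empty matched clusters are excluded with a count).

## Characterisation, composite score, survival

Cluster profiles report size, response proportions, responder rate, PD-L1
high fraction, immune-phenotype mix, mean TMB, per-gene mutation
frequencies, and mean expression of configurable panels (defaults:
T-activation CXCL9/CXCL10/CXCL13/GZMB; TGF-β TGFB1; the immunosuppressive
panel is user-supplied). Panel genes missing from the matrix are reported,
not fatal.

The composite immunogenomic score sums seven binary factors — activation
(+1): PD-L1 high, immune phenotype excluded or inflamed, TMB above the
cohort median, CXCL13 expression above the median, TP53 mutant; suppression
(−1): TGFB1 expression above the median, FGFR3 mutant — giving the range
[−2, +5]. **The combination rule is a reconstruction**: the factor list is
fixed but no weighting is canonical, so signed unit weights are the default
and both lists and weights are configurable. "High" for continuous factors
means strictly above the cohort median (ties low). Patients are grouped by
score quartiles (25/50/75 percentile cuts, linear interpolation, ties to the
lower group; heavily tied integer scores can give unbalanced groups, so
group sizes should be reported alongside).

Survival uses the Kaplan–Meier product-limit estimator (curve median =
smallest t with S(t) ≤ 0.5, undefined if never reached) and the log-rank
test (chi-square with k − 1 df for k groups), both via lifelines. Point
medians only; confidence intervals are out of core scope.

## Synthetic cohorts

The generator emulates the statistical skeleton of a bulk-RNA ICI cohort
with four planted subclasses:

- **Expression**: per-gene baselines Uniform(2, 8) on the log2 scale,
  Gaussian noise sd 1.0, and three 15-gene modules (T-cell activation,
  immunosuppression, TGF-β) shifted by `effect` (default 1.5 log2 units)
  in a subclass-specific pattern: T-activation high in subclasses 2 and 4,
  suppression high in 2, TGF-β high in 1 and 2. Marker symbols (CXCL9,
  CXCL10, CXCL13, GZMB, TGFB1) head their modules so panel and score
  defaults resolve. Values are clipped at 0 (log2(TPM+1) scale); expression
  is generated directly on the log scale, with an optional
  negative-binomial count layer for exercising TPM normalisation.
- **Clinical**: subclass proportions (0.34, 0.19, 0.25, 0.22); responder
  probabilities (0.00, 0.23, 0.77, 0.92); CR:PR and SD:PD splits 0.3/0.7
  and 0.25/0.75 within responders/non-responders; PD-L1-high and
  immune-phenotype probabilities and gamma-distributed TMB follow the same
  qualitative subclass pattern.
- **Mutations**: TP53 enriched in subclasses 2 and 4, FGFR3 in 1 and 3,
  RB1 in 2.
- **Survival**: exponential with per-subclass rates
  (0.122, 0.088, 0.033, 0.017 month⁻¹, i.e. medians ≈ 5.7/7.9/21/40
  months). Censoring: each sample is censored with probability
  `censor_rate` (default 0.3), in which case the observed time is
  Uniform(0, T); `censor_rate=0` observes every event.

What the generator does *not* emulate: count-level RNA-seq noise
(library-size gradients, GC bias, overdispersion structure), correlated
module membership, batch effects, continuous response phenotypes, or
informative censoring. Passing tests therefore demonstrate that the
pipeline recovers block-shift module structure under iid Gaussian noise —
necessary, not sufficient, for real cohorts.

At the default effect (1.5), the end-to-end pipeline recovers the four
planted subclasses at ARI 0.82–0.91 across seeds (n = 300), and recovery is
monotone in the effect size (≈0.15 at 0.5, ≈0.42 at 1.0, ≈0.98 at 2.0).

## Numerical and procedural choices

- Median dichotomization: "high" is strictly above the median; ties low
  (configurable).
- kNN ties broken by sample index; PCA signs fixed by leading loading;
  k-means uses 10 restarts with the run seed; all randomness flows from a
  single integer seed per run.
- BH adjustment via statsmodels; ARI via scikit-learn; Hungarian matching
  via scipy; KM/log-rank via lifelines — each validated in the test suite
  against brute-force or hand-computed oracles.
- Problem sizes in the test and acceptance workloads (n = 300 cohorts,
  20,000-gene prior-recovery simulation, 2,000-replicate log-rank null)
  were chosen to make the statistical checks sharp at desk scale.

## Known limitations

- The composite score's weighting is an explicit reconstruction (see
  above); conclusions about quartile survival ordering depend on it.
- The eigengap can be indecisive on weakly structured SNN graphs; the
  automatic refinement rule only fires at k = 3 and otherwise leaves
  sub-structure to explicit configuration.
- Replicate clusterings reuse the reference k; if the replicate eigengap
  disagrees, that disagreement is not surfaced in the stability report.
- Attributions are path-dependent TreeSHAP; interventional attributions
  (and hence the embedding) would differ where features correlate.
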