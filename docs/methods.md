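# Methods

`nacstrat` implements a machine-learning workflow for predicting response
to neoadjuvant chemotherapy (NAC) in muscle-invasive bladder cancer from
two data modalities: multicohort bulk transcriptomes and tabular digital
pathology (immunohistochemistry marker intensities quantified separately
in tumor and stroma compartments). All analyses run on synthetic data
with known ground truth, generated by the package's own simulator, so
every stage can be validated by parameter recovery rather than by
re-downloading patient data.

## The scientific problem

Roughly half of NAC-treated patients do not respond, and suffer toxicity
and surgical delay for nothing. The workflow asks two questions:

1. Can a gene-expression classifier trained on one small cohort predict
   response in independent cohorts profiled on different platforms?
2. Can a clinically manageable panel of 2–5 protein markers, selected
   from two-compartment pathology tables, stratify patients into
   predicted response groups with distinct survival?

## Synthetic data model (`syndata`)

**Transcriptomes.** Four cohorts (default sizes 16, 23, 38, 299 with
approximately balanced responder (R) / nonresponder (NR) labels) are
drawn on a latent Gaussian scale: gene-by-sample standard normals, with
`n_informative` (default 20) planted genes shifted by `effect_size`
(standardized units, default 1.0) in responders. Platform heterogeneity
is modeled by per-cohort affine distortions (`cohort_shift`,
`cohort_scale`) applied after the shift, and marginal shape by optional
exponentiation (`shape="lognormal"`, the default), so the planted class
separation survives as a monotone transform within each cohort. A single
informative gene therefore separates classes with theoretical AUC
Φ(d/√2), which the test suite verifies empirically.

**Pathology.** Two cohorts (NAC n=55, PCT n=36 by default; class
balances 34/55 and 11/36) with 74 markers × 2 compartments. Core
intensities are lognormal — exp(latent + core noise) — because DAB
optical densities are positive and right-skewed; `n_predictive` markers
per compartment carry a log-scale shift of `effect_size` (default 2.0)
in responders. Each patient contributes three replicate tissue-microarray
cores; the per-patient working value is the core mean.

**Survival.** Overall and progression-free survival are exponential
proportional-hazards times coupled to the *latent* response: responders
have hazard `baseline_hazard` (0.02/month), nonresponders
`baseline_hazard × hazard_ratio` (default HR 2.5); PFS uses a 1.5×
baseline. Censoring is an independent Uniform(0, b) time where b is
solved numerically (Brent's method) so the expected censored fraction of
the exponential mixture equals `censor_rate`. Consensus molecular
subtype labels are sampled at fixed proportions (18:10:11 for
LumP:LumU:Ba/Sq) as annotations only.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; fixtures round-trip losslessly through
plain-text TSV/GMT/JSON (floats are written at 17 significant digits and
parsed with pandas' `round_trip` option).

## Expression scaling (`scalers`)

Nine per-gene transforms: log2, log2+min-max, standard, min-max,
max-abs, robust, Yeo-Johnson power, normal-output quantile, and
RankGauss (rank → inverse normal CDF at (r − ½)/n). All transforms are
fitted along the sample axis, per cohort by default (pooled fitting is
available by concatenation). Constant genes map to 0 (standard, power)
or 0.5 (min-max-type), with a logged warning, instead of propagating
NaNs.

A **Gaussianity gate** retains methods whose scaled output has mean
absolute per-gene skewness ≤ 0.5 and mean absolute excess kurtosis
≤ 1.0. The outcome is data-dependent: on lognormal marginals the linear
rescalings (standard, min-max, …) keep their skew and fail, leaving the
shape-changing transforms (power, RankGauss, quantile when n is large).
A **premodeling** pass then evaluates each gated method with a 100-tree
random forest under stratified threefold cross-validated prediction for
every (cohort, classifier) combination, and selects the method with the
highest mean Matthews correlation coefficient (ties: higher mean F1,
then canonical method order).

## Gene-classifier extraction and reduction (`classifiers`)

Discovery cohorts are tiny, so per-sample prediction scores and gene
importances come from an **ensemble of 10 random forests × 100 trees**
(forest f seeded with seed+f), averaging out-of-bag probabilities and
impurity importances. Extraction sweeps the top-k genes (k = 5…30 by
mean importance), standardizes them, hierarchically clusters the samples
(Ward/Euclidean), cuts at two clusters and scores agreement with the
NR/R labels by the adjusted Rand index; the smallest k attaining the
maximum wins.

Reduction applies three sequential filters on Yeo-Johnson-scaled values:

1. **Mutual information** — plug-in MI between each 4-quantile-binned
   gene and the label; genes below θ_MI = 0.01 nats are dropped.
2. **Variance inflation factor** — while max VIF > θ_VIF = 10, drop the
   most collinear gene (ties: lexicographically larger ID), VIF computed
   by OLS of each gene on the rest.
3. **Cluster representatives** — if more than `target_max` (10) genes
   remain, genes are Ward-clustered and the highest-MI representative of
   each cluster kept. Redundancy here is judged on **within-class
   residuals** (per-gene class means removed before clustering): genes
   that co-vary only through the response signal are not redundant with
   each other, so the label-driven structure being selected *for* is
   excluded from the similarity used to remove redundancy. Without this,
   planted signal genes — correlated through the label by construction —
   collapse into a single cluster and the pipeline discards most of the
   true signal.

The reduction reports ΔAUC between logistic fits on the full and reduced
sets; |ΔAUC| < 0.2 is the acceptance rule. Logistic fits everywhere use
maximum likelihood stabilized by a very weak ridge (C = 10⁶) so the
optimum stays finite on separable tiny cohorts. `top10_refine` keeps at
most ten key genes by ensemble importance, and `build_union` forms the
deduplicated first-seen-order union of refined variants.

## Cross-cohort validation (`xcohort`)

Cohorts are harmonized to genes present everywhere whose scaled
distributions are pairwise comparable (Welch t-test p > 0.05; α = 0
degenerates to the presence filter). The validation design is **fully
enumerated**: every ordered (train, validation) pair of distinct cohorts
(remaining cohorts are tests) × classifier × variant (top-10, union) ×
model (weak-ridge logistic, depth-3 decision tree, 100-tree forest).
With 4 cohorts and 17 classifiers this is 17 × 2 × 3 × 12 = 1,224 runs.
Models fit on the training cohort only; all roles are scored with six
metrics computed from first principles: accuracy, recall, precision,
F1 (0/0 → 0), MCC (zero denominator → 0) and AUC via the tie-corrected
mid-rank Mann–Whitney statistic (undefined on single-class labels).

## Marker-panel optimization (`panelsel`)

- **RFECV**: recursive feature elimination under stratified threefold
  cross-validation; at each round the marker whose removal leaves the
  best remaining balanced accuracy is eliminated; rank = reverse
  elimination order (last survivor = rank 1).
- **Pools**: candidate pools of exactly 5 tumor + 5 stroma markers from
  repeated RFECV rankings with re-seeded fold assignments; duplicate
  pools are discarded within a bounded seed budget.
- **Stepwise search**: greedy forward selection and backward elimination
  over panel sizes 2–5, both base models (depth-3 tree, logistic), both
  data types (raw, per-marker z-scored), with mean threefold balanced
  accuracy as the criterion and lexicographic tie-breaks. The incumbent
  panel is replaced only by a strictly better configuration (ties: fewer
  markers, then lexicographic marker tuple). Balanced accuracy is used
  because the two cohorts' class balances differ markedly.

On pools built by RFECV at study scale (planted signal, n≈200), the
greedy search stays within 0.02 of the exhaustive best subset; on pure
noise the exhaustive maximum is inflated by selection (winner's curse)
and no greedy method can track it, which is why the oracle comparison is
run under the study conditions.

## Clinical statistics (`clinstats`)

- **Heuristic cutoff**: maximally selected chi-square dichotomization
  over midpoints of adjacent observed values (ties → smaller cutoff).
  This is deliberately anti-conservative and documented as such.
- **Odds ratios**: Wald 95% CI on the log scale; any zero cell triggers
  the Haldane–Anscombe +0.5 correction (flagged).
- **Backward stepwise logistic**: drop the largest Wald p until all
  remaining predictors have p < α; unstable fits fall back to a small
  ridge (α = 10⁻⁴) with Wald statistics from the penalized information
  matrix. α = 1 is the identity on the predictor set.
- **Marker ratios**: per-core marker/denominator ratios averaged per
  patient (ratio-then-mean), non-positive denominators skipped with a
  warning; NR vs R Welch t-tests and across-marker z-scores.
- **Survival**: Kaplan–Meier curves and two-group log-rank tests are
  delegated to `lifelines`; hand-computed product-limit and O−E/V
  oracles live in the test suite. Predicted response groups come from
  thresholding the fitted panel model's probabilities at 0.5; KM +
  log-rank comparisons are reported per cohort and pooled, for OS and
  PFS, with patients missing annotations excluded with a warning.

## Numerical and reproducibility choices

- All metrics have explicit edge conventions (0/0 → 0; AUC `None` on
  single-class labels) and are tested against brute-force and
  third-party oracles to 1e-12.
- Every stochastic step takes an explicit seed; derived seeds are
  simple offsets or `default_rng(seed).integers(0, 2³¹−1)` draws.
- Ties are broken deterministically everywhere (score first, then
  lexicographic identifier; smallest k / fewest markers preferred).

## Limitations

- The simulator plants independent Gaussian effects; it does not model
  gene–gene co-expression networks, batch structure within a cohort, or
  non-proportional hazards.
- The RFECV rank semantics follow the standard convention (features
  whose removal hurts most are ranked best); descriptions of the
  procedure in the clinical literature are sometimes worded invertedly.
- The maximally selected chi-square cutoff inflates type-I error of the
  subsequent test; no correction is applied, matching common clinical
  practice, and this is a property of the method, not a bug.
- Plug-in mutual information is upward-biased at small n; θ_MI = 0.01
  nats is therefore a weak filter on 40-sample cohorts, and the VIF and
  clustering stages do the substantive pruning there.
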