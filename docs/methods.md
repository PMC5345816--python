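# Methods

This note documents the models, conventions and numerical choices behind
`radsel`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A baseline FDG-PET study of a segmented tumor yields one SUV volume and
one binary mask per patient. The analysis cohort is small (the default
synthetic cohort is 65 patients) relative to the number of candidate
descriptors (61 by default: 16 clinical covariates, 19 first-order image
features, 26 texture indices), so the workflow is built around two
consecutive dimension reductions — a redundancy screen and a
forest-based relevance selection — followed by a permutation-validated
evaluation and, for survival, optimal-cutoff Kaplan-Meier analysis with
an explicit selection-bias correction.

## Quantization

Texture analysis and the histogram-based first-order features operate on
absolutely resampled gray levels

    level(i) = round(D × SUV(i)),    D = 0.5 SUV per level,

with **half-away-from-zero** rounding (1.5 → 2, 2.5 → 3). The rounding
rule is fixed and documented so that quantized fixtures are bit-stable;
"round" alone is ambiguous between banker's and away-from-zero
conventions. Absolute (fixed-step) resampling keeps a level's physical
meaning constant across patients, at the price of a dependence on
SUV_max; relative (min-max) resampling is intentionally not the default.

## First-order features

* **MTV** (cm³) is voxel count × voxel volume; **TLG** = MTV × SUV_mean.
* **SUV_peak** is the mean SUV in a 1 cm³ sphere centered on the hottest
  masked voxel, clipped to the mask (the dominant convention; the sphere
  radius is 6.2 mm).
* **Skewness** is the standardized third central moment; **kurtosis** is
  non-excess (a normal distribution scores 3). Both are population
  (biased) moments. A single-voxel or zero-variance region returns NaN
  for the moments — never a silent 0 — and COV is defined as 0 for a
  uniform region.
* **Energy/entropy** are computed on the normalized histogram of
  quantized levels (entropy in bits, 0·log 0 = 0), reusing the one
  quantization already defined rather than introducing a second binning.
* **SUV_x** is the minimum SUV among the ⌈x%·N⌉ hottest voxels; **V_x**
  is the percentage of masked voxels with SUV ≥ (x/100)·SUV_max.
* **Sphericity** is π^(1/3)(6V)^(2/3)/A. The default surface estimator
  counts exposed voxel faces weighted by their physical area: exact on
  boxes (a cube scores (π/6)^(1/3) ≈ 0.806) and fully deterministic, but
  it overestimates oblique surfaces — a digital ball converges to 2/3,
  not 1. A marching-cubes estimator (`method="mesh"`, after a 1-voxel
  Gaussian pre-smoothing of the binary grid) is provided for smooth
  shapes; it scores a radius-10 digital ball within 3% of 1. The default
  stays face counting because its values are exactly testable and the
  downstream selection only uses ranks.

## Texture matrices

All three constructions are computed inside the mask only, and gray
levels enter weighted formulas **1-based** (formula level = quantized
level + 1) so a region containing level 0 never divides by zero. Absent
intermediate levels are kept as zero rows, matching absolute-resampling
semantics.

* **GLCM** — for each of the 13 unique 3D directions at Chebyshev
  distance 1, symmetric co-occurrence counts of within-mask neighbor
  pairs are accumulated and normalized to a probability matrix; the 13
  matrices are averaged with equal weights. Normalize-then-average was
  chosen (the alternative, averaging raw counts, weights directions by
  their pair counts and is available in principle by building a single
  pooled matrix); directions with no valid pair in a thin region are
  skipped, and a region with no pair in any direction is an error.
  The 10 indices (variance, energy, entropy, correlation, dissimilarity,
  contrast, homogeneity with 1/(1+|i−j|) weights, inverse difference
  moment with 1/(1+(i−j)²) weights, cluster shade, cluster tendency) are
  all invariant to the level offset; correlation of a flat matrix is NaN.
* **GLSZM** — zones are maximal same-level connected components under
  **26-connectivity** (6-connectivity available); the matrix counts
  zones by (level, size). The 11 indices follow the standard size-zone
  formulas (SZE…LZHGE weight counts by i±2 and j±2 powers; ZP = zones /
  voxels; the two non-uniformity indices square the marginals). The
  conservation law Σ(count × size) = masked voxel count holds by
  construction and is property-tested.
* **GLDM** (neighborhood gray-tone difference family) — for every masked
  voxel with at least one masked 26-neighbor, the absolute difference
  between its level and the mean level of those neighbors is accumulated
  per level (s_i), alongside occurrence probabilities p_i. Coarseness,
  contrast, busyness, complexity and strength follow the Amadasun-style
  definitions; coarseness is capped at 10⁶ when Σ p_i s_i underflows,
  busyness is NaN when its denominator vanishes (single-level region),
  and a constant region has contrast 0.

**Degenerate-value policy.** Undefined indices propagate as NaN into the
feature table and are imputed by the per-column cohort median before any
selection stage. Clinical tumors are occasionally tiny or uniform; this
policy keeps them in the cohort without inventing a value of 0 that the
forest would treat as informative.

## Redundancy pre-selection

Tie-corrected Spearman ρ and two-sided P are computed for every feature
pair; an edge joins two features iff |ρ| ≥ θ (default 0.8) and P < 0.05
(raw — multiple-testing correction belongs to the outcome tests, not to
a redundancy screen). Groups are **connected components** of this graph:
transitive chaining is deliberate, since empirically observed redundancy
groups chain features that are not all mutually correlated. Each group
contributes its highest-priority member; the shipped priority list
encodes a robustness-to-reconstruction ordering (package data,
overridable) in which volume, simple intensity statistics, nutritional
covariates and the most reproducible texture indices outrank the
features known to track them. Ties break alphabetically. Raising θ can
only remove edges, so the retained count F_u is non-decreasing in θ
(property-tested).

## Forest selection

* **Importance** — mean decrease in impurity (Gini) of a 500-tree
  forest, the classical Breiman-forest default; permutation importance
  is available by configuration. Trees use `max_features="sqrt"`, no
  depth limit, unweighted classes (class weighting exposed in config).
* **Threshold rule** — retain features with CI **strictly** greater than
  10% of the maximum CI ("higher than"); with the published worked-example
  coefficients, strict vs non-strict is indistinguishable.
* **Subset search** — every candidate subset is scored by the OOB
  misclassification of a forest restricted to it. Up to 9 candidates all
  2⁹−1 subsets are enumerated; beyond that the search walks a recursive
  backward-elimination chain, dropping the lowest-CI feature at each
  step and scoring every subset along the chain. The winner minimizes
  OOB error with ties broken toward smaller subsets, then higher summed
  CI, then lexicographic order; the full search log is retained so the
  reported error is checkably the log minimum. Search-stage forests use
  75 trees (each sample is out-of-bag in ≈27 trees, a stable estimate at
  n = 65) — a runtime/stability trade-off that keeps a full pipeline run
  under half a minute on one CPU; the ranking and evaluation forests
  keep 500 trees.
* **HFS comparator** — greedy forward selection by 5-fold stratified
  cross-validated accuracy of a standardized linear-kernel SVM (C = 1),
  stopping when no addition strictly improves. This is a plain-forward
  approximation of the hierarchical SVM wrapper family and is labeled as
  such (`method="hfs_svm"`); its known failure mode (complementary
  features that are individually uninformative never enter) is
  documented by test.

## Evaluation

Random-permutation validation: each of 10 iterations draws a stratified
2/3 train / 1/3 test split (stratification preserves the cohort's class
mix in both partitions; unstratified splitting is a flag). On each split
a forest and a standardized linear SVM are trained on the subset;
test-split misclassification rates are recorded, and the forest's
class-1 probability — the subset "combined into one feature" — feeds ROC
analysis. AUC is the trapezoidal/rank AUC (ties credit 0.5, equal to the
Mann-Whitney U statistic scaled); sensitivity and specificity are read
at each iteration's own Youden-optimal cutoff (highest cutoff on ties)
and averaged across iterations, mirroring a mean ± SD presentation.

The univariate comparator applies a two-sided Mann-Whitney U test per
feature (exact where sample size and ties permit, normal approximation
with tie correction otherwise), Benjamini-Hochberg adjustment across the
feature set, and per-feature ROC at the optimal cutoff with oriented
AUC (max of AUC and 1−AUC). Method comparisons use the two-sided
Wilcoxon signed-rank test on paired per-iteration errors; an all-zero
difference vector returns P = 1 with a warning.

## Survival

* **Optimal cutoff** — candidates are midpoints between sorted unique
  values, restricted so each side keeps ≥ 10% of patients (the inner
  selection interval the minimal-P correction assumes; configurable).
  The winner maximizes |Youden's J| of the high-group indicator against
  the event flag, i.e. ROC-based dichotomization; ties keep the lower
  cutoff. "High" means values strictly above the cutoff, and the
  reported hazard ratio is high-vs-low.
* **Kaplan-Meier / log-rank** — the product-limit estimator per group
  (equal to the empirical survival function under no censoring,
  property-tested), a two-sided log-rank chi-square P, and the **O/E
  hazard ratio** (O1/E1)/(O0/E0) — no proportional-hazards regression is
  fitted, matching a KM-based reporting style. A group with zero events
  leaves the HR NaN (flagged undefined) while the P is still computed.
  Median survival is the first time the KM estimate drops to ≤ 0.5
  (NaN if never reached).
* **Minimal-P correction** — scanning cutoffs makes the selected
  log-rank P anti-conservative; the corrected value follows the
  Miller-Siegmund approximation popularized by Altman for "optimal"
  cutpoints:

      p_cor = φ(z)[(z − 1/z) ln((1−ε)²/ε²) + 4/z],  z = Φ⁻¹(1 − p_min/2)

  with ε the selection fraction at each tail (default 0.05, the 5–95%
  interval; 0.10 gives the 10–90% variant). The approximation is valid
  for small p_min; at or above 0.1 the corrected value saturates at 1
  with a warning, and the result is floored at p_min so correction never
  *de*flates a P-value. A simulation test verifies that under a null
  exponential model the raw selected P exceeds the nominal level while
  the corrected type-I error stays ≤ 0.10 at nominal 0.05 (approximate
  control: the correction assumes min-P selection over the full
  interval, slightly different from Youden selection).

## Pipeline

`run_predictive` classifies the binary response label;
`run_prognostic` classifies death-within-horizon (default 36 months) —
patients censored before the horizon have an indeterminate label and are
excluded from classifier training with a logged count — then adds the
per-feature univariate KM comparator (optimal cutoff → log-rank → Altman
→ BH across features) on the full cohort, and a KM contrast of the
cohort split by the classifier's **out-of-bag** predicted labels (an
out-of-sample choice; resubstitution labels would overstate separation).
Every stochastic stage derives its seed from the run configuration, so a
manifest reproduces all artifacts bit-identically; reruns with a new
output directory never mutate old artifacts.

## Synthetic data

* **Phantoms** — an ellipsoidal mask (default semi-axes 15×15×20 mm ≈
  18.8 cm³, a realistic locally advanced esophageal lesion) on a
  4×4×2 mm grid; SUV = base (8.0) + a unit-variance correlated Gaussian
  field scaled by the heterogeneity amplitude, smoothed with a 5 mm FWHM
  Gaussian mimicking a reconstruction filter, clipped at 0; background
  1.0 outside. The scanner-like smoothing is applied to the
  heterogeneity component only so the mask boundary stays crisp and a
  zero-amplitude phantom is genuinely uniform. The generator does *not*
  model Poisson sinogram noise, reconstruction artifacts, partial-volume
  spill-over, or lesion-shape variety — tests passing on phantoms
  demonstrate correctness of the feature computations, not robustness to
  PET physics.
* **Cohorts** — features are drawn from a multivariate normal with
  block-constant within-block correlation (Gaussian copula rather than
  replaying any empirical grouping; the default preset uses 9 blocks of
  sizes 2,3,2,2,2,4,12,12,3 at ρ = 0.95, which leaves 28 of 61 features
  uncorrelated). Binary response at 63% prevalence; informative features
  receive class-conditional mean shifts stated in SD units. Survival is
  exponential with log-hazard linear in the standardized feature draws
  (baseline median 23 months) and independent uniform censoring whose
  upper bound is calibrated by bisection so the expected censored
  fraction hits the target (default 37%). Censoring independent of
  covariates is a documented simplification — adequate for testing the
  estimators, not a model of informative dropout.

## Problem sizes used by the checks

The test suite and acceptance script run at sizes chosen to exercise the
statistics meaningfully on one CPU: texture oracle equivalence on 200
random 4×4×4 regions with ≤5 levels (tolerance 1e-10); grouping recovery
on 20 planted 3-block cohorts; selection recovery over 20 full pipeline
runs at n = 65 with 28 candidate features; null calibration with 2000
Mann-Whitney simulations and 200–300 optimal-cutoff survival
simulations; HR recovery over 50 cohorts of n = 200.

## Known limitations

* The feature-name registry and default priority list target the
  61-feature clinical-plus-PET panel; other panels need a caller-supplied
  priority list (the pipeline falls back to table order).
* The HFS comparator is an approximation of the hierarchical SVM wrapper
  it stands in for; only its greedy-forward behavior is guaranteed.
* The O/E hazard ratio is biased toward 1 relative to a Cox estimate in
  small samples with heavy censoring; it is reported because it pairs
  naturally with the log-rank table.
* Beyond 9 candidates the subset search is a chain search guided by
  importance, not exhaustive; a subset whose value is purely
  interactive (each member unimportant marginally) can be missed.
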