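# Methods

This document defines every computational convention in `perirad` precisely
enough to reimplement it.  No empirical performance claims are made here;
numbers quoted are definitional (counts, formulas, thresholds) and are pinned
by the test suite.

## 1. Phantom cohort

Each case is a 3-D volume on a grid of configurable shape and spacing
(default 96 × 96 × 48 voxels at 0.9 × 0.9 × 2.0 mm).  Construction:

1. **Background**: constant level plus white Gaussian noise.
2. **Texture field**: white noise smoothed with a Gaussian kernel of
   subtype-specific correlation length, scaled by a subtype-specific
   contrast, added inside and around the tumor.
3. **Tumor**: a randomly oriented ellipsoid with semi-axes drawn uniformly
   from a configurable range; cases whose in-plane diameter falls below
   10 mm are redrawn (mirroring the clinical exclusion of sub-centimeter
   lesions).
4. **Peritumoral rim**: an additive term decaying with the Euclidean
   distance transform outside the tumor, with subtype-specific width and
   amplitude.
5. **Clinical covariates**: age, tumor size, background parenchymal
   enhancement, fibroglandular tissue, margin, axillary-lymph-node short
   diameter, firmness, mobility, and menopausal status, sampled with
   subtype-dependent log-odds shifts.

A fraction of cases receives perturbed repeat segmentations (same reader
second sitting, and a second reader) produced by randomly toggling boundary
voxels; perturbation magnitude is bounded so that Dice overlap stays high.
Seeds are derived by `numpy.random.SeedSequence` spawning and reduced
modulo 2³¹, so cohorts are deterministic in (profiles, n, seed).

Default subtype prevalences are 0.694 / 0.140 / 0.166
(HR-positive / HER2-enriched / TNBC).

## 2. Image preparation

* **Resampling** to 1 mm isotropic voxels: linear interpolation for
  intensities, nearest-neighbor for masks.
* **Normalization** maps the volume min → 1 and max → 4097 linearly.
* **Peritumoral rings**: for distances d ∈ {2, 4, 6, 8} mm, the ring at d is
  the set of non-tumor voxels whose distance to the tumor is in
  (d − 2, d] mm, computed per axial slice ("in-plane", the default) or in
  3-D.  Rings are clipped to the image; a fully clipped ring is an error.

## 3. Filter bank (14 image types)

With m the maximum absolute intensity of the input image:

| type | definition |
|---|---|
| original | identity |
| square | x² / m |
| squareroot | √(m·x) |
| logarithm | m · log(x + 1) / log(m + 1) |
| exponential | exp(x · log m / m) |
| log-sigma-3mm | Laplacian of Gaussian, σ = 3 mm (physical units) |
| wavelet-LLL … HHH | 8 bands of a one-level stationary coiflet-1 transform |

Wavelet band letters are ordered (x, y, z); L is the approximation filter and
H the detail filter along that axis.

## 4. Feature engine

Per ROI, 1,316 features: 14 shape features (from the original mask geometry)
plus 93 features on each of the 14 image types, named
`<imageType>_<family>_<feature>`:

* 18 first-order statistics (population variance; Pearson kurtosis, i.e.
  non-excess),
* 24 gray-level co-occurrence (GLCM),
* 16 gray-level run-length (GLRLM),
* 16 gray-level size-zone (GLSZM),
* 14 gray-level dependence (GLDM),
* 5 neighborhood gray-tone difference (NGTDM).

Conventions:

* **Discretization**: fixed bin width (default 25) applied to the ROI
  intensities; level k covers ((k−1)·w, k·w] anchored at zero.
* **GLCM**: 13 unique 3-D directions at distance 1, symmetric accumulation,
  features computed per direction then averaged over directions with
  non-empty matrices.  The gray-level count Ng is ROI-wide (zero rows are
  kept), which defines Idmn/Idn normalization and the MCC spectrum; a
  direction whose matrix concentrates on one gray level contributes an MCC
  second eigenvalue of 0.
* **GLRLM**: runs are maximal straight segments of equal level along each of
  the 13 directions; matrices are averaged over directions.
* **GLSZM**: zones are 26-connected components of equal level.
* **GLDM**: dependence of a voxel is the number of 26-neighbors within α = 0
  of its level, plus itself.
* **NGTDM**: mean absolute difference from the mean of valid 26-neighbors.

Degenerate single-gray-level ROIs use fixed conventions (Correlation = 1,
MCC = 1, entropies = 0) rather than NaN.  Every feature value is asserted
finite at extraction time.

## 5. Feature selection

Applied to training data only, strictly nested, with a recorded trace:

1. **Reproducibility**: ICC(2,1) (two-way random effects, absolute
   agreement, single rater),

   ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

   computed intra-reader (two sittings) and inter-reader (two readers) on the
   resegmented subset; a feature survives if both ICCs exceed 0.75.
2. **Max-abs normalization**: each feature divided by its training-cohort
   maximum absolute value; scales are frozen and reapplied to test cohorts
   (test values may leave [−1, 1]).  All-zero columns are dropped with a
   warning.
3. **ANOVA-F screen**: keep the top ⌊0.2 · m⌋ features by F statistic
   (stable sort, so ties resolve in column order).  From 1,089 candidates
   this retains exactly 217; 1,089 of 1,316 prints as 82.8%.
4. **L1-SVM**: a linear SVM with L1 penalty refit under 10 seeds; features
   with nonzero coefficients in a majority of fits are selected.  An empty
   selection raises an error advising a larger C.

## 6. Subtype models

Tasks: 1 = HR-positive vs others, 2 = HER2-enriched vs others, 3 = TNBC vs
others, 4 = ternary.  The cohort is split 7 : 3, stratified by subtype with
largest-remainder rounding (327 cases split 228 / 99).

* **IRM / PRM**: SVM (RBF kernel by default) on the selected intratumoral /
  peritumoral features; probabilities via Platt scaling.
* **Optimal ring**: the ring distance with the highest validation AUC;
  ties resolve to the smallest distance.
* **CIPRM**: logistic regression on the IRM and optimal-ring PRM scores.
* **CM**: logistic regression on the clinical predictors that survive a
  univariate screen (t-test/ANOVA for numeric, chi-square for categorical)
  followed by a multivariate logistic model; if the Wald machinery
  degenerates (non-convergence, singular or non-finite covariance), a
  weak-ridge fallback is used and the univariate survivors are kept.
* **CCRM**: logistic regression on clinical predictors plus the combined
  radiomics score; collinear and constant columns are dropped; separation
  triggers a ridge fallback (flagged on the result object).
* **Nomogram**: linear predictor mapped to points such that the dominant
  predictor spans 0–100 over its observed range; total points invert
  exactly to the model probability.

All model objects follow a statsmodels-like shape: a specification object,
a `fit(seed)` method, and an immutable results object with `summary()`.

## 7. Evaluation

* **AUC**: DeLong's method; the point estimate equals the concordant-pair
  fraction (ties count ½).  Variance via structural components; 95% CI by
  normal approximation, clipped to [0, 1].
* **DeLong test**: paired (covariance of structural components) or unpaired
  z-test for two AUCs.
* **Operating point**: Youden's J on training scores; ties resolve to the
  highest threshold.  The training threshold is frozen and reused on test
  cohorts.
* **Calibration**: deciles of predicted probability, observed vs mean
  predicted, plus a logistic recalibration slope/intercept.
* **Decision curves**: net benefit NB(t) = TP/n − FP/n · t/(1−t) over
  t ∈ {0.01, …, 0.99}; treat-all reduces to
  prevalence − (1 − prevalence) · t/(1 − t).
* **Confusion metrics**: accuracy and support-weighted F1 for the ternary
  task.

## 8. Workflow

`RunConfig` (YAML/JSON round-trip) drives `run_pipeline`: phantom cohort →
preprocessing → feature extraction (derived images shared across the
intratumoral and ring masks of a case) → ICC filter → split → per-task
selection, models, and evaluation → JSON report plus CSV artifacts.  One
master seed is spawned into per-stage seeds, so a run is a pure function of
its config and reruns are byte-identical.  The `perirad` CLI exposes
`show-config`, `generate`, and `run-all`; config errors exit with status 2,
stage failures with status 3.
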