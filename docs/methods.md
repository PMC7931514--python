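# Methods

`fetrad` re-implements, as a tested pipeline on synthetic data, a radiomics
prognostic analysis for recurrent glioblastoma imaged with amino-acid
(FET) PET before re-irradiation: semi-automatic tumor segmentation from SUV
images, extraction of a 135-entry radiomics feature vector, phantom-based
feature screening, and survival / recurrence-location modelling. This note
records the models, the defaults and why, what the synthetic data does and
does not emulate, and the numerical choices made where the design was open.

## Segmentation model

Contouring is a three-step procedure on an SUV image with voxel spacing in
mm (the reference geometry is 2×2×2 mm voxels):

1. **Background estimate.** Two spheres of constant diameter (default 30 mm,
   a config parameter — the clinically used diameter is not standardized)
   are placed by the user in cerebrum and cerebellum; SUV(Bg) is the mean of
   the two per-sphere means (not the pooled voxel mean), so unequal sphere
   voxel counts do not weight the estimate.
2. **Threshold.** `v_threshold` = voxels with SUV ≥ 1.8 × SUV(Bg). The
   comparison is inclusive: a boundary voxel at exactly the threshold is
   tumor. An expert exclusion mask (vessels, extracerebral uptake) is a
   user input — the pipeline never auto-classifies non-tumor uptake — and
   `v_pet` = `v_threshold` AND NOT exclusion.
3. **Derived contours.** `v_pet3mm` expands `v_pet` by a 3 mm Euclidean
   margin (exact Euclidean distance transform under the true, possibly
   anisotropic spacing; a voxel is included iff its center is within 3 mm of
   an in-mask voxel center). `v_petmax` is the connected component of
   `v_pet` containing the global SUV maximum; contiguity is 26-connectivity
   (configurable to 6), ties on the maximum break to the lexicographically
   first voxel. A 4 cc spherical background contour `v_bg` is placed
   disjoint from `v_pet3mm`, deterministically (the candidate center
   farthest from the avoided region).

Sphere membership everywhere is the voxel-center-inside test with no
partial-volume weighting. The nesting `v_petmax ⊆ v_pet ⊆ v_pet3mm` is
asserted on every run.

## Feature catalogue (135 names, manifest `fetrad-135-v1`)

* **Histogram (9):** SUV_min/max/mean/median, population variance, skewness,
  excess kurtosis, plus energy and entropy of the fixed-bin-width histogram.
* **Shape (6):** volume (voxel count × voxel volume), face-counting surface
  area, sphericity π^⅓(6V)^⅔/A, compactness 36πV²/A³, and eccentricity
  √(1−λ_min/λ_max) / elongation √(λ₂/λ_max) from the voxel-center
  covariance eigenvalues (in mm).
* **Texture (40):** GLCM (9), GLRLM (13), GLSZM (13), NGTDM (5), computed on
  the fixed-bin-width discretized ROI.
* **Variants:** the same 40 texture features on the equal-probability
  quantized ROI (prefix `Q`) and on the wavelet band-pass filtered volume,
  re-discretized with the same bin width (prefix `WF_`). 9+6+3×40 = 135.

There is no single standard 135-feature list; this catalogue is frozen in a
versioned manifest and contains every feature name the reporting convention
of this analysis design relies on (SZLGE,
Busyness, WF_TS, QVariance_CM, Eccentricity, GLV, GLV2, WF_GLV, QAcor,
QHGZE, QSZHGE, QGLN2, QHGRE, QSRHGE, QLRHGE, SUV_min, SUV_mean). `WF_TS` denotes NGTDM texture Strength on the
wavelet-filtered volume; `GLV` is the run-matrix and `GLV2` the zone-matrix
gray-level variance (the `2` suffix pairing with the zone features GLN2).

### Discretization

Fixed bin width W = 0.01 SUV anchored at the ROI minimum:
level(x) = ⌊(SUV(x) − min)/W⌋ + 1, giving Ng = ⌊range/W⌋ + 1 bins (a few
hundred for typical tumor contours). Anchoring at the ROI minimum makes the
level map invariant to adding a constant. The equal-probability quantizer
assigns levels by rank to 64 levels (the common histogram-equalization default); tied values share the level of
their first occurrence, and empty levels are compacted.

### Wavelet band-pass filter

One decimated 3D DWT level (coiflet-1, symmetric padding), re-weighting the
six mixed sub-bands (those with both low- and high-pass axes) relative to
LLL and HHH, then inverting. The printed weight ratio "1:2 between band-pass
sub-bands and other sub-bands" does not fix its orientation; the default
attenuates band-pass sub-bands by ½ and `orientation="boost"` selects
weight 2. Weights are normalized so that unit ratio is the exact identity
(perfect reconstruction, verified to 1e−10). Because of decimation phase,
the filtered volume — hence the `WF_` features — is equivariant under axis
permutations but **not** under axis reflections; the invariance suite
asserts all 48 grid symmetries for the other 95 features and the 6
permutations for `WF_`.

### Texture matrices

All four matrices follow the 3D volumetric definitions of the image
biomarker standardization literature. GLCM and GLRLM use the 13 unique
direction offsets at Chebyshev distance 1 with **merged** aggregation (pool
counts over directions, then normalize), chosen over per-direction averaging
for rotational stability; the direction set is closed under grid symmetries,
so merged-matrix features are invariant under the 48 axis
permutations/reflections. GLSZM zones and the NGTDM neighborhood use
26-connectivity restricted to the mask; an NGTDM voxel with no in-mask
neighbor contributes zero difference but still counts in the level
occupancy. NGTDM pair sums (Busyness denominator, Strength numerator) run
over ordered pairs of occupied levels. Degenerate inputs (single-voxel ROI,
single occupied level, zero denominators) yield NaN — an explicit
"undefined" flag that downstream statistics drop pairwise — never an
exception or a silent omission. Every matrix and every derived feature is
checked against an independent brute-force enumeration (explicit voxel/pair
loops, flood fill) on 200 random ROIs.

## Feature screening

* **Scanner robustness:** paired Wilcoxon signed-rank across the 18 phantom
  contours (12 background spheres of 5.7–8.4 cc, pooled with the 6 fillable
  spheres segmented at 40% of their maximum uptake) rendered under two
  scanner profiles; *robust* ⇔ p ≥ 0.05 (uncorrected α — Bonferroni is
  reserved for the tumor-vs-background family, the one place a multi-feature
  discovery claim is made). The exact signed-rank null distribution is used for ≤ 25
  untied pairs, the tie-corrected normal approximation above; all-zero
  differences give p = 1 ("robust" by convention).
* **Size dependence:** Spearman correlation of each feature with the contour
  voxel count over 102 background contours with log-uniform volumes
  0.8–234 cc; *dependent* ⇔ p < 0.05 AND |r| > 0.8. The absolute value is
  deliberate: a strong negative correlation is equally disqualifying.
* **Tumor vs background:** per-feature paired Wilcoxon between a tumor
  contour and the 4 cc background sphere, at the Bonferroni level α/K with
  K the number of features tested.
* **Added value:** a feature is independent of the conventional indices iff
  it is not strongly Spearman-correlated (same rule) with either SUV_max or
  volume.

All Spearman-based decisions are invariant under strictly monotone feature
transforms, and screening is a pure function of (feature table, config).

## Survival and recurrence-location models

* **Univariate screen:** each feature is dichotomized at the cohort median
  (ties to the low group; the median cut is deterministic and configurable) and the two groups compared
  with the standard two-group log-rank test (1-df χ²), implemented directly
  from the risk table and cross-checked against lifelines. The family
  threshold is Bonferroni α/K with K = the number of features actually
  tested after the robustness restriction, recorded in the run report.
* **Redundancy pruning:** candidates passing p < 0.05 are joined by edges
  where strongly Spearman-correlated; connected components form groups and
  each group is represented by its smallest-log-rank-p member (ties by
  name).
* **Radiomics signature:** representatives enter a multivariate Cox
  proportional-hazards fit (lifelines, Efron tie handling; coefficients are
  refit jointly after pruning, the standard construction). Reported: β, HR = e^β with 95% CI, and the three overall tests
  — likelihood ratio (lifelines), Wald (β′I⁻¹β, hand-assembled), and the
  score test at β = 0 (hypergeometric variance with finite-population tie
  correction, the multivariate log-rank generalization). The signature risk
  score is β′x; its Kaplan–Meier display splits the score at the median.
  Fewer than 5 events per covariate warns but does not fail (a 32-subject
  cohort legitimately violates the comfort margin).
* **Recurrence location (RL):** label 1 ⇔ more than 50% of the recurrence
  volume lies inside the initial `v_pet` (a mask helper implements this
  rule); the label is defined only for subjects with observed progression.
  The logistic model uses imbalance-adjusted bootstrap resampling: each of
  `n_boot` (default 1000) resamples draws n subjects with the class chosen
  uniformly and the subject uniformly within class, so both classes appear
  at equal expected proportion. Coefficients are the mean over bootstrap
  fits; AUC and sensitivity (at the 0.5 probability cut) are 0.632+
  combinations of apparent and out-of-bag performance. The 0.632+ point
  estimate floors the out-of-bag term at the chance level, which gives it a
  small (~+0.04 at n = 32, measured) positive bias for a truly
  uninformative predictor; the out-of-bag AUC itself is unbiased at the
  null (0.508 ± 0.008 over 150 replicate cohorts) and is the quantity used
  for calibration checks. Resamples whose in-bag or out-of-bag set lacks a
  class are redrawn (bounded retries).

The log-rank χ² test is known to be mildly anti-conservative at n = 32
(rejection ≈ 0.056–0.061 at nominal 0.05 with 0–15% censoring; reproduced
identically with R `survival::survdiff`, so this is a property of the test,
not of this implementation).

## Synthetic data: what it emulates and what it does not

* **Brain scans:** uniform background SUV (default 1.0) plus spherical hot
  lesions (contrast 2.5–5× background, radius up to the 1–6 cm diameters
  typical of visible recurrences), an intra-lesion multiplicative
  heterogeneity field (1 + f, f a Gaussian random field scaled to a chosen
  SD and correlation length, clipped at 0.1), Gaussian PSF blur (reference
  4.8 mm FWHM) and additive Gaussian SUV noise. Background magnitude and
  tumor-to-background ratios are asserted as plausible, not derived from any
  cohort. The noise is additive Gaussian in SUV, not Poisson in counts: the
  pipeline consumes reconstructed SUV images, and this suffices for
  robustness testing. No anatomy, no vessels (the exclusion-mask step is
  exercised with synthetic masks), no reconstruction artifacts.
* **Phantom:** six spheres (0.52–25 cc, the standard fillable set) in a warm
  background box; identical geometry rendered under two scanner profiles
  (4.8 mm/σ0.04 and 5.2 mm/σ0.05 — mildly different, as
  accreditation-harmonized systems are). No lung insert or torso shell:
  only sphere/background statistics matter downstream.
* **Outcome cohorts:** feature values are independent Normals; TTP and OS
  are exponential with hazard h₀·exp(β′x) (constant baseline — the Cox
  stage is hazard-shape-agnostic, so this suffices for recovery tests);
  censoring is independent exponential with its hazard solved by bisection
  to hit the requested expected censoring fraction; the RL label is
  Bernoulli(logistic(γ′x)). Defaults mirror a 32-patient re-irradiation
  cohort scale: median TTP ≈ 91 days (15% censored), median OS ≈ 296 days
  (30% censored), with SZLGE driving both earlier progression (β = 0.8) and
  in-field recurrence (γ = 1) — the qualitative pattern the pipeline is
  meant to detect.

Consequently, passing tests show that the *pipeline machinery* is correct
and calibrated under controlled conditions; they cannot show that real
FET-PET radiomics carry prognostic signal, that the texture model matches
real tumor heterogeneity, or that cross-scanner robustness on real
reconstructions matches the synthetic profiles.

## Problem sizes and determinism

Simulation-based checks use: 1000 null cohorts (n = 32) for log-rank
calibration; 60 replicate cohorts × 1000 bootstrap resamples for null-AUC
calibration; 500 cohorts of n = 500 for Cox recovery (bias < 10%, CI
coverage 92–98%); 100 cohorts of n = 200 for end-to-end selection power;
200 random ROIs for oracle equivalence. The demo runs 16 synthetic brain
subjects on 48³ grids, the 18-contour robustness set, 30 size contours of
0.8–30 cc and a 32-subject outcome cohort; the full 102-contour, 234 cc
size family runs in `analysis/01_phantom_screening.py`. Every generator and
resampler takes an explicit seed; a pipeline run is a pure function of its
JSON config, and rerunning a config reproduces every output byte for byte
(no timestamps in outputs; the manifest records the config hash, seed,
catalogue version and per-stage row counts).

## Known limitations

* The 135-name catalogue is a reconstruction; real analyses may have used a
  different base-feature/variant split.
* `WF_` features are not reflection-invariant (decimated DWT phase).
* The 0.632+ performance estimate is optimistic by construction for
  near-chance predictors (see above); compare `auc_oob` when calibration
  matters.
* Phantom and brain simulations share an idealized Gaussian blur/noise
  model; reconstruction-specific texture (e.g. iterative-reconstruction
  correlations) is not emulated.
* No clinical-covariate adjustment, no proportional-hazards diagnostics
  beyond convergence, no external-validation logic.
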