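# Methods

This note documents the models, conventions and parameter choices behind
`parotid_radiomics`, in the order the pipeline runs them.

## Synthetic cohort model

The generator emulates the statistical structure of a parotid-tumor
radiomics cohort, not MRI physics (no k-space, no diffusion model, no
DICOM). Each lesion is an ellipsoid embedded in a 32×32×16-voxel ROI at
0.7×0.7×3.0 mm spacing (clinical in-plane resolution, thick slices).
Diameters are drawn uniformly on 12–19 mm: the lower bound enforces the
"> 1 cm" inclusion rule with margin, and the upper bound is what the
default ROI grid (22.4 mm in-plane extent) can hold; no claim of realism
attaches to this distribution. About 20% of patients carry a second
same-class lesion; splits are by lesion, matching how such cohorts are
counted.

Lesion texture is a class-conditional Gaussian random field: white noise
smoothed with a Gaussian kernel of correlation length ℓ, rescaled to mean
μ and standard deviation σ. The default `EffectProfile` plants three
class contrasts chosen to load on distinct feature families:

| contrast | WT | MT (default) | targeted family |
|---|---|---|---|
| gray-level mean | μ = 300 | μ − 1.0·σ | GLRLM HighGrayLevelRunEmphasis |
| correlation length | ℓ = 2.0 mm | 1.6·ℓ | GLSZM zone/gray-level variance |
| intensity variance | σ = 60 | 1.8·σ² | first-order RootMeanSquared |

With `EffectProfile.null()` all three ratios collapse and the classes are
exchangeable by construction. The T2-like volume receives additive noise
(sd 10), a mild multiplicative coil-inhomogeneity field (±8%, exercised
by the bias corrector) and a positive clip; the ADC-like volume is an
affine anti-correlated transform of the T2 cellularity field clipped to
0.4–2.5 (units of 10⁻³ mm²/s), so both sequences carry the class signal,
as in real parotid imaging where cell-dense tissue is T2-heterogeneous
and diffusion-restricted.

Re-segmentation is emulated by shifting the mask boundary (zero level of
the signed Euclidean distance) by a smooth random field bounded by
±jitter. The default jitter of one in-plane voxel (0.7 mm) produces ICC
values that straddle the 0.85 gate, so the stability filter is exercised
non-trivially rather than passing or failing everything.

What the generator does **not** emulate: scanner- and protocol-dependent
intensity non-stationarity across a cohort, anatomic context (vessels,
necrosis, gland boundary), histology-specific texture, partial-volume
effects at lesion rims. Passing tests therefore demonstrate that the
pipeline recovers the *kind* of statistical structure it assumes, not
that it reproduces clinical effect sizes.

## Preprocessing

Order is fixed: bias correction → whole-image z-score → ROI outlier
removal → isotropic resampling → filters → discretization.

* **Bias correction** is a log-domain polynomial fit (total degree 3)
  over the mask support, divided out as a multiplicative field with unit
  geometric mean; the ROI arithmetic mean is restored exactly afterwards.
  This captures the contract of inhomogeneity correction (removal of a
  smooth multiplicative field, validated against planted fields) without
  the iterative B-spline machinery of full N4. It is applied to the
  T2-like volume only by default: an ADC map is a computed parameter map,
  for which multiplicative coil bias is not a meaningful model
  (`bias_on: both` restores the symmetric behavior).
* **Normalization** is a whole-image z-score scaled to sd = 100. A plain
  z-score (sd = 1) combined with the fixed bin width of 25 would collapse
  every ROI into a single gray level; scale 100 yields ~24 levels over
  ±3σ, the standard pairing of z-scoring with W = 25 in radiomics
  platforms.
* **Outlier removal** excludes ROI voxels beyond μ±3σ of the *ROI*
  statistics (features are ROI-scoped) from the mask; intensities are
  never clamped. The step errors rather than empty the mask.
* **Resampling** to 1×1×1 mm³ uses cubic B-spline interpolation for
  images and linear interpolation + 0.5 threshold for masks (smoother
  boundaries than nearest-neighbor when upsampling 3 mm slices; the
  choice is fixed so shape features are reproducible). Output dimensions
  are `round(dim·spacing/target)` per axis under a voxel-centre
  convention, preserving world extent to within one voxel.
* **Discretization** assigns `level = floor((x − min_ROI)/W) + 1`
  (anchored at the ROI minimum), applied independently to every filtered
  image with the same W. Levels are invariant to adding multiples of W.

## Filter bank

Eleven images per sequence: the original; 8 sub-bands (LLL…HHH, letters
in x,y,z order) of a single-level *undecimated* 3D wavelet transform with
Coiflet-1 taps and symmetric (mirror) boundaries — undecimated so
sub-band voxels stay aligned with the mask; and scale-normalized (σ²·∇²G)
Laplacian-of-Gaussian responses at σ = 3 mm (fine) and 5 mm (coarse),
with σ converted to voxels per axis. LoG kernels use 8σ support so a
constant image maps to zero at 1e-6 relative; σ below half a voxel is
rejected as undersampled. Both operators are linear and
translation-equivariant (tested).

## Feature definitions and conventions

Feature names follow `{sequence}|{filter}|{family}|{feature}`. Per-family
counts are fixed at 14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16
GLSZM, 14 GLDM, 5 NGTDM = 1037 per sequence over the 11 images (shape is
computed once from the shared mask and reported under both sequences).

Conventions chosen where the standard definitions leave freedom, each
guarded by unit tests and mirrored exactly in the brute-force oracles:

* GLCM/GLRLM matrices are accumulated over the 13 unique distance-1
  directions of the 26-neighborhood and features are averaged per
  direction (directions with no valid pair are skipped); GLSZM zones and
  GLDM dependence use full 26-connectivity; GLDM α = 0.
* Matrix rows/columns are indexed by the gray levels *present* in the
  ROI, with the actual level values as weights.
* Degenerate single-gray-level ROIs: GLCM Correlation = MCC = 1,
  Imc1 = Imc2 = 0; NGTDM Busyness/Strength/Contrast = 0 and Coarseness
  saturates at 10⁶ (ε = 10⁻⁶ denominators); first-order
  Skewness/Kurtosis of a constant ROI are 0. No feature is ever NaN —
  `extract_all` errors on any non-finite value, naming the feature.
* NGTDM counts only voxels with ≥ 1 in-mask neighbor.
* First-order Entropy/Uniformity use the discretized levels; all other
  first-order features use raw intensities. Kurtosis is the uncorrected
  Pearson moment ratio (normal = 3).
* Shape: surface area and volume come from a marching-cubes
  triangulation of the zero-padded binary mask at iso-level 0.5.
  Triangulating a *binary* grid chamfers the voxel staircase, which
  inflates the surface area of curved bodies by a few percent (a
  digitized ball reads sphericity ≈ 0.91–0.96 rather than 1); volumes
  are accurate to well under 1%. No mask smoothing is applied — the
  estimator is deterministic and standard. Axis lengths are 4√λ of the
  voxel point-cloud PCA eigenvalues; degenerate masks report 0.

## Selection cascade

* **ICC gate**: ICC(A,1) — two-way mixed effects, absolute agreement,
  single measures — computed per feature over the re-segmented subset
  (30 lesions by default, chosen before splitting); strict ICC > 0.85.
  Zero-variance features get ICC 0 with a warning.
* **Univariate screen**: two-sided Mann–Whitney U (exact enumeration when
  both groups ≤ 8, else normal approximation with tie correction), then
  Benjamini–Hochberg step-up adjustment jointly across all features of
  both sequences (a per-sequence mode is available); retain q < 0.05.
  The screen runs on training rows only.
* **Redundancy pruning**: Spearman pairs with |ρ| > 0.9, processed in
  decreasing |ρ| order; where both members are still alive the larger-p
  member is eliminated (ties: lexicographically later name), making the
  outcome deterministic.
* **LASSO**: features are z-standardized with training means/sds, which
  are stored in the model and applied unchanged to test data (no
  leakage). The λ path runs geometrically from λ_max (the smallest λ
  zeroing all coefficients) down 3 decades over 50 points; λ minimizes
  the mean 10-fold stratified cross-validated binomial deviance
  ("minimum" rule; a 1-SE rule is available). The final refit's nonzero
  coefficients, intercept and standardization constitute the
  `ScoreModel`. WT is encoded 1, so scores are higher for Warthin's
  tumors.

## Evaluation

The test allocation is ceil(n/4) per class (66+40 → 79 train / 27 test
with the 49/30/17/10 class breakdown). AUC is the Mann–Whitney estimator
(ties ½) reported on the ≥ 0.5 orientation, with DeLong variance for the
95% CI and the p-value against 0.5. The cut-off maximizes Youden's J over
midpoints of observed scores (ties resolved toward the score median), and
malignancy is called *below* the cut-off — MT is the positive class.
Sensitivity/specificity get exact Clopper–Pearson intervals; likelihood
ratios get log-method intervals with a Haldane 0.5 correction for zero
cells and one-sided intervals when a ratio is infinite.

## Simulation studies

Two pre-registered experiments validate the pipeline end to end
(`parotid_radiomics.experiments`):

* **Planted-effect recovery** runs the full study condition (106 lesions,
  32×32×16 ROIs, default effect profile). A planted family counts as
  recovered when at least one of its signature features (any
  sequence/filter) is BH-significant at the screen stage; the later
  stages intentionally keep only one representative per correlated
  cluster, so membership of the final sparse model is not the criterion.
* **Null calibration** repeats a zero-effect cohort 20 times at reduced
  scale (20+20 lesions, 16×16×8 ROIs, filter-free extraction) — the
  calibration properties checked (BH false-positive fraction ≤ α, score
  AUC compatible with 0.5) do not depend on cohort scale or the filter
  bank, and the reduction keeps the study inexpensive. When the screen
  or the LASSO retains nothing on a null cohort, the score is constant
  and its AUC is recorded as 0.5.

## Known limitations

* The bias corrector models the field as a global degree-3 polynomial;
  strongly non-polynomial inhomogeneity would be only partially removed.
* Binary-mask marching cubes biases curvature-dependent shape features
  (Sphericity, SurfaceArea) by a few percent, consistently.
* The wavelet family and the normalization scale are conventions, not
  measurements; results are reported under the documented defaults and
  both are configurable.
* T2 and ADC volumes are assumed voxel-aligned (the mask is transferred,
  not registered); no inter-scanner harmonization is implemented.
* The cohort generator's effect profile is a stylized three-axis
  contrast; real WT/MT texture differences are richer and weaker, so
  synthetic AUCs should not be read as clinical performance estimates.
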