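# Methods

## Problem setting

Sonographic estimated fetal weight (EFW) is computed by plugging fetal
biometrics — head circumference (HC), biparietal diameter (BPD), abdominal
circumference (AC), femur length (FL) — and gestational age (GA) into a
population-specific linear formula. This package covers the whole chain:
measuring the biometrics from 2-D images, evaluating the weight formulas,
and the regression/evaluation statistics used to develop and judge such
formulas. Because no image dataset is distributed with the models, a
phantom generator with analytic ground truth stands in for clinical images
wherever a measurement has to be validated.

## Phantom model

Skull and abdominal-wall cross-sections appear in B-mode imaging as bright
elliptical rims on a darker background; the ossified femoral shaft as a
bright elongated bar. The generator renders exactly these primitives on a
512×512 canvas (background 0.1, foreground 0.9, 0.2 mm/px by default —
plausible obstetric-scan scale; all configurable):

- **head/abdomen**: the region between an outer ellipse with semi-axes
  (a, b) and an inner ellipse (a−t, b−t), t the wall thickness. The truth
  semi-axes refer to the *outer* boundary. Truth values: HC/AC = outer
  perimeter (complete elliptic integral) × mm/px; outer-to-outer BPD =
  2b × mm/px; outer-to-inner BPD = (2b − t) × mm/px.
- **femur**: a rectangle of length L and width W rotated by a free angle;
  truth FL = L × mm/px.

Edges are rendered hard (no anti-aliasing) so truth boundaries are
unambiguous for recall metrics. Speckle — the granular multiplicative
interference noise of ultrasound — is modelled first-order as
`clip(img·(1 + σ·G), 0, 1)` with G i.i.d. standard normal; (spec, seed)
determines the image bit-for-bit, and zeroing σ with the same seed yields
the matching clean reference.

**What the phantom does not emulate:** point-spread blur, attenuation,
acoustic shadowing, neighbouring anatomy, probe-angle-dependent dropout,
non-isotropic pixels. Passing the recovery suites therefore shows the
geometry/denoising machinery is correct and noise-robust at realistic
contrast; it does not certify clinical accuracy on real scans, where
segmentation is the dominant failure mode.

## Preprocessing

RGB input is collapsed with BT.601 luma weights (0.299, 0.587, 0.114);
DICOM input supplies mm/px from its pixel-spacing tag when present.
Denoising is wavelet soft thresholding: db4, 3 decomposition levels,
universal (VisuShrink) threshold σ√(2 ln n) with σ estimated from the
median absolute deviation of the finest diagonal detail band (all three
configurable; BayesShrink available as `threshold_rule="bayes"`). A
noise-free image estimates σ = 0 and passes through unchanged. Fidelity
metrics are PSNR = 10·log10(range²/MSE) (inf for identical images — a
legitimate degenerate comparison, not an error) and mean local SSIM with
the standard 7×7 window and K1 = 0.01, K2 = 0.03. Published average
denoising figures on clinical data (e.g. ~59 dB PSNR) depend on the source
dataset; the suite asserts the *improvement property* instead: denoising
raises PSNR against the clean reference on every speckled phantom.

## Biometry measurement

Stage sequence (head): grayscale → denoise → adaptive threshold → largest
connected component → Canny edges → convex hull → ellipse fit. The
abdomen prepends a white top-hat (opening residue, structuring-element
radius 15 px) and a linear contrast stretch, which suppress soft-tissue
glare broader than the wall; the femur replaces the ellipse stages with a
minimum-area rotated rectangle.

Numerical choices that matter:

- **Adaptive threshold**: foreground iff intensity > local mean (51 px
  square window) + 0.02. Window must exceed the wall thickness (else the
  local mean saturates at the rim level) and be small against illumination
  gradients; 51 px satisfies both at the default scale.
- **Contour**: the convex hull is taken over the Canny edge *point
  coordinates* and resampled at ~1 px spacing, rather than re-rasterized;
  this keeps the contour localized on the outer boundary to sub-pixel
  accuracy (rasterizing the hull and re-tracing it inflates each semi-axis
  by ~0.75 px, a 1.5% HC bias at a = 60 px). The hull also closes gaps a
  partially imaged wall leaves in the rim.
- **Ellipse fit**: direct least-squares algebraic conic fit with ellipse
  constraint — deterministic and exact on noise-free samples. The test
  suite cross-checks it against an independent brute-force geometric
  grid-search minimizer on jittered instances.
- **Circumference**: Ramanujan's second approximation, relative error
  < 5·10⁻⁴ up to axis ratio 10 — negligible against measurement noise, so
  no quadrature in the hot path.
- **BPD convention**: the minor axis of the skull ellipse gives the
  outer-to-outer diameter; the conventional outer-to-inner reading
  subtracts one wall thickness, estimated as the median radial width of
  the segmented rim over 180 angular bins (+1 px for pixel footprint).
  `bpd_convention = {"outer_to_inner" (default), "minor_axis"}` exposes
  both, since clinical sources use both wordings.
- **Rectangle/contour pixel-footprint correction**: +1 px on each rotated-
  rectangle side (centre-to-centre spans underestimate the occupied area
  by one pixel).
- **Degenerate inputs**: an empty segmentation raises `NoObjectError`; a
  featureless abdomen image is not contrast-stretched (stretch floor 0.01)
  so numerical residue cannot fabricate foreground. Implausible fits —
  head axis ratio > 2.5, object below 0.5% of the image — are *flagged*
  (`implausible_fit`, `small_object`), not rejected. Component ties break
  toward the image centre.

Verified invariants: doubling mm/px doubles all reported mm; 90° rotation
changes HC/AC/FL by ≤ 1%; median |relative error| over randomized
20-phantom suites is ≤ 2% clean and ≤ 5% at speckle σ = 0.2 (measured:
0.5–0.9% clean, 1.2–3.7% speckled; femur is the noisiest because specks
touching the bar perturb the minimum-area rectangle).

## Weight models and categories

Both published formulas are evaluated as exact linear maps. Their units
are taken as AC/BPD/FL in centimetres, GA in weeks and output in grams —
the only dimensionally coherent assignment (33 cm AC contributes 239.9 g in
model 2; mm inputs would exceed 6000 g at term). Biometry produced in mm is
converted automatically. The ethnicity code E of model 1 has no published
codebook; the default maps Oromo=1, Amhara=2, SNNPR=3, other=4 (the order
the groups are usually listed for this population) and is explicitly
provisional — supply your own coding when fitting new data. Estimates
outside 500–6000 g carry an `implausible_weight` flag.

Weight categories use strict bounds for "normal" (2500 g < w < 4000 g), so
the boundary weights fall in the adjacent classes; ≥ 4500 g raises a
`severe_macrosomia` sub-flag rather than a sixth class.

## Regression statistics

`fit_mlr` is ordinary least squares with intercept (statsmodels backend)
reporting every block a model-development paper prints. Identities
enforced by tests: t = B/SE; standardized β = B·sd(x)/sd(y);
VIF = 1/tolerance with tolerance = 1 − R² of each predictor on the others;
SS_total = SS_reg + SS_res; summary values recomputed through
`anova_from_ss` from the fit's own sums of squares match to 1e-9 relative.
`anova_from_ss` also reconstructs F, R², adjusted R² and the standard error
of the estimate from printed ANOVA tables alone, which is how published
fits are checked for internal consistency without the raw cohort.
p-values use exact t/F distributions. Missing data: listwise deletion with
a logged count. Sample size rounds P(1−P)Z²/d² to the nearest integer
(384.16 → 384). Pearson screening defaults to |r| ≥ 0.3 and p ≤ 0.05
(configurable; published model-development reports rarely state the cut),
reporting constant candidates as "undefined" rather than r = 0.

The simulated development cohort (`simulate_model2_cohort`) mirrors the
study conditions: n = 384; GA ~ N(35.26, 3.04²) truncated to 30–42 weeks;
AC/BPD/FL grow linearly with GA at textbook third-trimester rates
(1.0, 0.18, 0.175 cm/week) with individual variation (sd 1.5, 0.35,
0.30 cm), giving realistic moderate collinearity; outcome = image-model
linear predictor + N(0, 349²) g residuals (the development fit's standard
error of the estimate). Over 50 such cohorts the per-coefficient 95% CI
coverage must lie in [0.88, 1.0]; note that demanding *every* one of the
250 coefficient estimates within 3 SE is a ~50/50 event under correct
sampling (expected ~0.7 exceedances), so coverage is the robust check and
the maximum |z| is reported as a diagnostic.

## Percentage-error evaluation

PE = 100·(estimated − actual)/actual, positive for overestimation.
"MPE" is the mean *absolute* PE (the magnitude-based convention the
bucket tables imply); the signed mean is reported separately as bias.
Buckets: accepted |PE| < 10 (strict, per the "< 10%" convention);
10 ≤ |PE| ≤ 15 over/under by sign; |PE| > 15 extreme. Counts are exact;
percents are recomputed to 2 dp (no attempt to chase rounding quirks in
published tables). The report is invariant to case order and to common
rescaling of estimates and actuals.

## Problem sizes

Default validation sizes — 20 phantoms per structure per noise level, 10
denoising seeds, 50 simulated cohorts of n = 384, an 85-case evaluation
cohort — match the study-scale conditions while keeping the full suite
around a minute on one core.

## Known limitations

- Single fetus, single structure per image; no standard-plane detection.
- Phantom realism is deliberately minimal (see above).
- The ethnicity codebook and the formula units cannot be validated against
  any published source; both are configurable and documented as choices.
- Third-party EFW formulas (Hadlock, Jordaan, …) are not built in; the
  comparison harness accepts any user-supplied `LinearModel`.
- Durbin–Watson is reported without significance bounds.
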