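# Methods

## The question and the measurement

A radiomic feature is *reproducible* across acquisition settings when
its distribution over identical ROIs does not change with the setting.
We measure this with paired nonparametric tests per (tissue class,
feature): Wilcoxon signed-rank for two settings, Friedman for three or
more, Bonferroni-corrected over the 92 features within a tissue class.
The DiffFeatureRatio pools the significant fraction over classes; by
default the *adjusted* p-values enter the ratio (a `use_raw` flag probes
the uncorrected behaviour, since either convention is defensible).

## Synthetic acquisition model

All study designs start from a clean ground-truth volume and are
"acquired" per setting as

    observed(x) = gain · b(x) · resample(clean)(x) + offset + ε(x)

with `b` a smooth random multiplicative field (Gaussian-filtered white
noise at 80 mm scale, rescaled to grid mean exactly 1 and peak deviation
exactly `bias_amplitude`), `resample` cubic-b-spline resampling to the
setting's voxel spacing (`fov·10/matrix` mm in-plane, 4 mm slices), and
`ε ~ N(0, noise_sigma²)` i.i.d. Gaussian noise. Gaussian rather than
Rician noise keeps the model analytically transparent; at the SNRs used
here (tissue means 100–200, σ 2–3) the Rician correction is negligible.
ROI geometry is defined once in physical coordinates and rasterized per
setting, so equal-spacing settings carry voxel-identical masks — the
paired design that attributes every feature difference to the injected
effect.

The default paired study emulates a 1.5T-vs-3T scanner change: gain 1.0
vs 1.8, noise σ 2 vs 3, bias amplitude 0.05 in both arms, equal FOV
(24 cm) and matrix. The 1.8× gain produces the large raw intensity gap
between arms; the noise difference is the texture-level effect.

### Phantoms

The homogeneous phantom holds nine tubes of distinct constant means (60,
85, …, 260 — equally spaced, ≥ 5× the noise σ apart so the classes stay
identifiable). The heterogeneous phantom holds six tubes of correlated
Gaussian texture with per-tube variance (16–81) *and* per-tube
correlation length (3–12 mm): because fixed-bin-number discretization
cancels pure amplitude differences, distinct materials must differ in
texture *scale* to be texture-identifiable. In-tube texture is
standardized against its own in-tube moments, so the in-tube sample
variance equals the configured variance exactly before noise. Circular
per-slice ROIs nearly fill the tubes (radius 0.9 of the tube radius),
and ROI pixel radii scale inversely with voxel spacing, mirroring
protocols that fix larger pixel radii at coarser FOVs.

### Brain-like volumes

An ellipsoidal "head" with three compartments in T1 ordering
(WM 200 > GM 120 > CSF 40, texture σ 5 at 5 mm correlation) plus a
corpus-callosum band: a WM subregion around the midline sampled in the
sagittal plane. The default protocol emits 60 ROIs per acquisition — 20
WM and 20 GM circles in transverse slices, 20 CC circles in sagittal
planes — placed by seeded rejection sampling inside eroded compartment
masks (bounded retries, then an explicit placement error). ROI radius is
0.055 of the in-plane matrix (the usual manual-ROI scale, 14 px at 256),
and the default study uses matrix 128 with six subjects: at this scale
the paired tests have realistic power (120 pairs per tissue class) while
a full pipeline condition runs in ~13 s.

What the generator does **not** emulate: anatomy (gyri, partial volume,
asymmetries), MR physics (relaxation-time contrast changes between field
strengths, Rician noise floors, ghosting/motion), inter-subject
registration error (pairs are co-registered by construction), and
pathology. Passing tests therefore demonstrate correctness of the
methods and the direction of the scanner-effect findings, not clinical
effect sizes.

## Preprocessing

The bias corrector is a log-domain low-pass estimator, not a
re-implementation of the full iterative N4 algorithm: log-intensity is
smoothed within the mask by normalized Gaussian convolution (FWHM 40 mm
default) on a shrink-factor-2 grid, iterated on the residual to a 1e-4
tolerance, exponentiated, and normalized to mask mean 1 (so correction
preserves the mask-mean intensity and is idempotent to < 1% RMS). This
removes the synthetic smooth fields this package generates; exact
numerical equivalence with N4 is a non-goal.

Resampling uses `scipy.ndimage.map_coordinates`: cubic b-spline for
images, order-0 (nearest) for masks — masks stay strictly boolean. Voxel
centers sit at `origin + (index + 0.5)·spacing` with the origin anchored
at the input origin; output shape is `ceil(extent/target)`. Resampling
to the native spacing short-circuits to the identity. B-spline boundary
handling makes constants exact everywhere and degree-1 ramps exact in
the interior (prefilter boundary effects decay exponentially over ~10
samples).

## Intensity normalization

Six methods, parameters estimated inside the brain (or foreground) mask,
the transform applied to the whole volume (mask-restricted application
would be an equally defensible convention; whole-volume keeps the
background interpretable):

1. **Z-Score** — population μ, σ over the mask.
2. **WhiteStripe** — μ, σ over the stripe of voxels between the
   (q−τ, q+τ) intensity quantiles around the WM mode (τ = 0.05 default,
   the original convention). When the window hits a quantile boundary it
   shifts to keep its full 2τ width, so τ = 0.5 degenerates exactly to
   Z-Score.
3–5. **FCM / GMM / KDE** — `I_norm = c·I/μ` with μ the WM mean (fuzzy
   c-means with fuzzifier 2, tolerance 1e-5, quantile-initialized;
   3-component Gaussian mixture, best of 5 seeded starts) or the WM peak
   (Gaussian KDE, Scott's rule, highest-intensity local maximum carrying
   ≥ 10% of the peak density — the mass threshold rejects numerical
   wiggles in the tails). WM is the brightest class, the T1 convention;
   `c` defaults to 1.
6. **Nyúl** — landmarks at percentiles {1, 10, 20, …, 90, 99}, each
   training image mapped affinely to the standard range [1, 100],
   landmarks averaged, application by piecewise-linear interpolation
   with linear extension beyond the outer landmarks. The learned scale
   is invariant to per-image affine transforms, and the applied map is
   monotone.

All six neutralize a global positive affine intensity change between
paired volumes — which is precisely why they close the image-level gap
between field strengths yet barely move the DiffFeatureRatio: the
fixed-bin-number discretization already makes every texture feature
affine-invariant, so the features that normalization could fix were
never the ones driving the ratio.

## Feature extraction

92 features per single-slice ROI under 32-bin fixed-bin-number
discretization (`level = 1 + floor(n_bins·(x−min)/(max−min))`, maximum
assigned the top bin, constant ROI → level 1). The registry follows the
IBSI-aligned default-enabled lists of the standard open-source
extractors: 18 first-order (standard deviation excluded as redundant
with variance), 23 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM. Texture
matrices are built in-plane at pixel distance 1; GLCM (symmetric) and
GLRLM are computed for the four 2D directions and averaged with equal
weights; zones and dependences use 8-connectivity; GLDM dependence size
is 1 + the number of neighbours within α (= 0) of the center level, so
sizes run 1..9. Degenerate conventions: GLCM Correlation → 1 and
MCC → 1 on a flat ROI, Imc1/Imc2 → 0, NGTDM Contrast → 0, Coarseness →
the 1e6 sentinel, Busyness/Strength → 0; first-order skewness/kurtosis
→ 0 at zero variance. Percentiles use linear interpolation. Every family
is verified against an independent brute-force oracle (pair enumeration,
run scanning, flood fill, per-pixel neighbourhood means, dependence
counting) to 1e-9 on random grids.

## ComBat

Per feature v and batch i, `y = α_v + γ_iv + δ_iv ε`, no covariates
(all samples are paired, so there is no biological design to protect).
α is the sample-size-weighted grand mean and σ_v the pooled
within-batch residual sd. After standardization, the *standard* variant
uses the per-batch sample mean/sd directly; the *parametric* variant
shrinks via a normal prior on γ and inverse-gamma prior on δ² with
method-of-moments hyperparameters and iterative conditional updates
(tolerance 1e-4, the convention of the reference implementations); the
*non-parametric* variant computes posterior expectations by
likelihood-weighted averaging over the other features' raw estimates
(O(V²) per batch — trivial at 92 features). Harmonization is applied
per tissue class: the same feature carries different additive and
multiplicative scanner effects in different tissues, and a pooled fit
demonstrably leaves residual effects behind (tested).

A structural property worth knowing: when the true batch effect is
homogeneous across features, the method-of-moments prior variance
equals the sampling variance of γ̂, the EB weight is 1/2, and the
harmonized batch means retain half the sampling noise of γ̂
(sd ≈ 0.05σ at n = 200/batch). The standard variant, by contrast,
equalizes sample batch means exactly. Tests bound the EB variants
accordingly; the standard variant is held to the exact criterion.

## Evaluation layer

Wilcoxon drops zero differences (all-zero → p = 1 by convention; at the
feature-table level, fewer than 5 informative pairs also reports p = 1,
since no difference is detectable); the exact null distribution is used
for n ≤ 25 without ties, otherwise the normal approximation with tie and
continuity corrections. Friedman uses midranks with tie correction and
the χ²(k−1) approximation. Bonferroni multiplies by an explicit family
size — the 92 features within one tissue class — and caps at 1; the
ratio then pools significant counts across classes.

Type-I calibration of this layer is checked by feeding it independent
per-feature null pairs (2000 tests), where the binomial 99% band around
α = 0.05 is the correct reference. An image-level global null is *not*
used for the binomial check: features extracted from the same ROIs are
strongly correlated, which inflates the variance of the significant
fraction far beyond binomial, and a bound that assumes independence
would reject on correlated data at any sample size.

PCA views standardize features column-wise (constant columns dropped
with a warning). On the phantom, class identifiability is asserted via
cross-validated linear-discriminant accuracy on the standardized
features and the between-class R² of the leading component, rather than
a silhouette threshold in 3-component space: the 92 features carry
strong redundancy and estimation-noise factors that rival the class
factor among the top components, so clusters are not compact there even
when the class information is fully recoverable (accuracy 1.0 after
per-class ComBat vs 0.60 raw — harmonization merges the per-setting
subclusters while preserving the tube identity).

## Problem sizes and determinism

Default runs: brain study 6 subjects × 2 settings × 60 ROIs at matrix
128 (~13 s per pipeline condition); phantoms 8–10 slices. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (config, seed) reproduce CSV
outputs bit-identically (floats are written at 12 significant digits).

## Known limitations

- The acquisition model is affine-plus-smooth-field-plus-noise; it does
  not emulate contrast (relaxation-time) changes between field
  strengths, so the raw DiffFeatureRatio here is driven by gain and
  noise differences only.
- The bias corrector targets smooth synthetic fields; it is not an N4
  replacement for clinical data.
- 2D, single-slice ROIs only; no image filters; fixed-bin-number only
  (fixed-bin-size discretization would change texture invariances).
- Nonparametric ComBat is quadratic in the feature count; fine at 92,
  not meant for thousands of features.
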