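# Methods

This note documents the models, parameter choices and numerical decisions
behind `petrad`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator produces the study conditions every downstream stage is
evaluated under: 49 "patients" carrying 60 lesions on an isotropic 4 mm
grid, three lesion archetypes (blob on a dark background, heterogeneous,
liver-like with background uptake at 60 % of the lesion), four simulated
operator contours per lesion calibrated to a mean pairwise Dice of 0.78.

**Lesion geometry.** Each lesion is a randomly oriented ellipsoid. The
base radius is log-uniform over 5–34 mm with per-axis anisotropy factors
in 0.75–1.3, giving truth volumes from ~0.5 mL to beyond 160 mL — the
span from small lesions (below the ~16 mL scale at which edge-based
segmentation gets hard) to large ones. The exact ellipsoid indicator is
kept as the ground-truth mask and never touches the image border
(guard margin 3 voxels), so every 26-neighbourhood is defined.

**Imaging model.** The voxelized activity (ellipsoid indicator ×
heterogeneity field) is convolved with a Gaussian point-spread function of
σ = 3 mm, the effective post-reconstruction resolution of the 4 mm-voxel
analog PET system being emulated (~7 mm FWHM). Two consequences are
deliberate physics, not artifacts: the half-maximum contour of a large
lesion coincides with the true boundary, and small lesions exhibit
partial-volume depression of their measured SUVmax because the PSF is
applied to the activity without renormalization.

**Uptake.** The unblurred peak SUV is drawn lognormally (median 15,
σ_log = 0.3) with a mild positive volume coupling (exponent 0.4 on
V/9 mL), clipped to [2, 60]. The coupling encodes the empirical
covariation of lesion size and tracer avidity in receptor-expressing
tumor cohorts; with uptake drawn independently of size, the raw-scale
Pearson correlation between volume-proportional features (TLSRE) and
volume is mathematically bounded near 0.87 by the uptake coefficient of
variation, which would contradict the volume dominance such features show
in real cohorts.

**Heterogeneity and background.** Intra-lesion heterogeneity is a
mean-one exponentiated Gaussian random field (correlation length 8 mm;
log-amplitude 0.15 / 0.5 / 0.3 for blob / heterogeneous / liver-like),
producing the low-uptake internal regions that drive low-gray-level zone
features. The background is not flat: tissue texture is modelled as a
mean-one lognormal field (log-amplitude 0.25) multiplying the archetype
background level (1.5 / 2.5 SUV for blob / heterogeneous; solved for the
liver-like archetype so that mean lesion / far-background uptake is
exactly 1/0.6 in the noiseless image). A flat background would make the
in-VOI minimum identical for every delineation, structurally removing the
mechanism by which per-VOI min–max rescaling interacts with segmentation.
Sensor noise is Gaussian, smoothed at 4 mm and scaled to σ = 0.3 SUV.

**Operator simulation.** An operator mask is
`{x : sd(x) ≤ bias_o + a·u_o(x)}`, where `sd` is the signed Euclidean
distance to the truth boundary (mm), `u_o` a smooth unit-variance random
field (correlation 12 mm) and `bias_o` a per-operator outward offset
(+1.2/+0.9/+0.6/+0.3 voxels). The biases are all outward because manual
PET delineation predominantly over-contours into the blur halo; operators
rarely cut into the bright core, and their disagreement concentrates in
how much low-uptake rim is included. The jitter amplitude `a` is set by
`calibrate_operator_jitter`, a bisection on the cohort mean pairwise
inter-operator Dice (target 0.78); the shipped default (0.75 voxels) is
the calibrated value under the remaining defaults. Masks are kept
connected (largest component) and a draw that empties a mask is retried
with damped amplitude.

**Randomness.** One child RNG stream per lesion, spawned from the master
seed, so changing one lesion's parameters never reshuffles the others.
Fixed seed ⇒ byte-identical cohort.

**What the generator does not emulate.** No sinogram/OSEM reconstruction
(noise is stationary Gaussian, not reconstruction-correlated), no
respiratory motion, no anatomical context (organs, vessels), no
multi-lesion interaction within a patient. Tests passing on this phantom
therefore demonstrate the correctness and internal consistency of the
pipeline and the direction of the robustness effects, not their
patient-cohort magnitudes.

## Segmentation

**SAEB (semi-automatic edge-based) level set.** The single operator input
is the seed point (for synthetic lesions, the truth centroid — mimicking
a click on the lesion center). Iteration 0 is a sphere of radius 2 voxels
at the seed. The curve evolves under a hybrid two-phase energy

    E = (1 − λ_edge) · CV(SUV image) + λ_edge · CV(edge image),

where CV is the piecewise-constant two-phase (Chan–Vese) region energy
and the edge image is the Gaussian-smoothed gradient magnitude
(σ = 2 mm). Both region terms are normalized by their image's dynamic
range, making the result invariant under positive rescaling of the image.

The evolution is a morphological scheme rather than a continuous PDE: at
each iteration the combined force flips only the voxels on the current
boundary, followed by one binary median-filter pass as curvature
regularization; convergence is declared when the fraction of voxels
changing side stays below 10⁻³ for three iterations (max 300). A final
smoothing-free "polish" phase (≤ 10 iterations) lets the pure force
reclaim corner voxels the median filter shaves off a digital ball — this
is what makes a noiseless sphere recoverable exactly. A median pass that
would annihilate a very small region is skipped, so few-voxel lesions
survive regularization.

`λ_edge` defaults to **0.3**. With equal weighting (0.5) the Chan–Vese
term on the edge image annexes the outer half of the gradient ridge —
the ridge is centered on the true boundary, so treating "high edge
response" as foreground systematically dilates the contour (~50 % volume
overshoot on a blurred sphere). At 0.3 the edge term still sharpens
localization on low-contrast (liver-like) lesions without dominating.

Degenerate inputs: an image without contrast raises an empty-result
error; a collapsed evolution likewise; non-convergence returns the mask
with a warning; the connected component containing (or nearest) the seed
is returned.

**Threshold VOIs.** `threshold_voi` keeps the parent voxels with
SUV ≥ (pct/100) × in-parent SUVmax. The threshold is relative to the
parent VOI's own maximum, so surrounding physiological uptake cannot
leak in; the result always contains the max-SUV voxel and thresholds are
antitone (VOI40 ⊆ VOI30 ⊆ VOI20 ⊆ parent). No connectivity post-filter is
applied by default.

**STAPLE.** Standard EM: posterior W of foreground from the rater
decisions under current (p, q); M-step re-estimates per-rater sensitivity
and specificity. Initialization p = q = 0.99; the prior is the voxel-wise
mean of the rater masks (spatially varying); computation is restricted to
the union bounding box plus a 5-voxel margin so that distant background
cannot inflate specificity; probabilities are clipped at 10⁻⁷; convergence
when max |Δ(p, q)| < 10⁻⁵. Empty/full raters and complementary-rater
inputs are flagged degenerate instead of crashing. The consensus mask is
W ≥ 0.5 and, in the pipeline, is built from the four operator masks only
(the level set is excluded, since it is one of the methods being judged).

## Discretization

Absolute mode maps SUV to levels `floor((SUV − low)/w) + 1` with
`w = (high − low)/n_bins`; default 64 bins over [0, 60] SUV, i.e. bin
width 60/64 = 0.9375 SUV (sometimes quoted rounded as 0.95). Bins are
half-open with the top bin closed; values outside the bounds clamp to the
boundary levels, since lesions may exceed the range. Relative mode uses
the same formula with the in-VOI min/max; a constant VOI maps to level 1
and is flagged single-gray-level. Absolute mode is one global map —
identical SUVs get identical levels in every VOI — which is precisely why
it decouples texture features from the delineation-dependent VOI range.

## Features

51 features in LifeX-style naming. Conventions that vary between
implementations, fixed here:

* quartiles: linear interpolation of the empirical distribution;
* SUVpeak: mean over a digital sphere (0.5 mL / 1 mL) of voxels whose
  centers lie within the sphere radius; the sphere may extend beyond the
  mask but not beyond the image (out-of-image portions are excluded).
  Because of this image context, feature extraction is crop-invariant for
  crops that keep at least the sphere reach (1 voxel at 4 mm spacing) of
  margin;
* histogram skewness/kurtosis are moments of the *discretized* level
  distribution; kurtosis is non-excess (normal → 3);
* surface area: marching cubes at the 0.5 iso-level of the binary mask
  pre-smoothed with a σ = 0.7 voxel Gaussian — on a digital ball this
  reproduces the analytic sphere area within ~1 %, where a raw binary
  mesh overestimates by ~9 %. The mask is tight-cropped before meshing so
  the result is independent of surrounding array extent. Sphericity
  = π^(1/3)(6V)^(2/3)/A; Compacity = A^(3/2)/V (monotone inverse of
  compactness). Any positive rescaling of Compacity would cancel in every
  ICC/COVᴸ/Pearson output, so the exact constant is immaterial to the
  analysis;
* texture matrices merge counts over the 13 unique distance-1 directions
  into one matrix per family before features are computed; the GLCM is
  symmetrized (both pair orders counted); zones use 26-connectivity —
  note an in-plane checkerboard therefore forms one zone per level, not
  singletons; NGLDM accumulates |level − mean(in-mask 26-neighbours)| per
  gray level, and its Coarseness/Contrast/Busyness follow the standard
  neighbourhood-difference formulas;
* run percentage RP = N_runs/(13·N_vox); zone percentage ZP =
  N_zones/N_vox; matrix gray axes span levels 1..max-observed (trailing
  empty rows cannot affect row-sum features);
* texture features are NaN when the VOI has fewer than 8 voxels
  (`min_voxels_texture`) or a single occupied gray level; an optional
  compatibility flag replaces Sphericity/Compacity with 0 for VOIs under
  64 voxels, emulating a known software artifact — off by default because
  the zero is an artifact, not a measurement.

Every texture feature is verified against brute-force enumeration oracles
(explicit pair/run/zone/neighbourhood loops) to 10⁻¹⁰ relative tolerance
on randomized small VOIs.

## Robustness statistics

The ICC is the two-way mixed-effects consistency form: with lesions as
rows and methods as columns, BMS and RMS come from the additive ANOVA
decomposition (no interaction), ICC = (BMS − RMS)/(BMS + (N−1)·RMS).
Rows containing any NaN are dropped (complete cases) — pairwise deletion
would not match the single-equation two-mean-square form. Methods are
fixed effects. Zero total variance defines ICC = 1 with a degenerate
flag. The implementation is cross-checked against an independent
statistical library's two-way mixed consistency ICC.

COVᴸ = 100·sd/mean per lesion (sample sd). The mean guard (|mean| below
10⁻¹² of the value scale → NaN) prevents features with tiny, sign-mixed
values from producing unbounded dispersion; undefined values are excluded
from median summaries with counts reported.

Pearson profiles average each feature across segmentations within a
lesion before correlating with the lesion's volume or SUVmax (absolute
discretization, no threshold).

Robustness classes: high (ICC > 0.9), robust (0.8 < ICC ≤ 0.9), moderate
(0.5 ≤ ICC ≤ 0.8), poor (< 0.5), undefined for NaN.

## Pipeline

The experiment grid is explicit: 5 segmentations × 4 thresholds
(none/20/30/40, "none" encoded as a fourth level) × 2 discretizations
= 40 rows per lesion. Three comparison axes: across segmentations at
fixed (threshold, discretization); across thresholds at fixed
segmentation under absolute discretization; across the two
discretizations at fixed segmentation, no threshold. Axis-level summaries
for the latter two report the median ICC per feature across the five
segmentation methods. Thresholds are re-derived per segmentation from
that VOI's own maximum. Per-lesion failures (e.g. a collapsed level set)
are logged and excluded; the run continues and the summary enumerates
exclusions. Everything is deterministic given the master seed.

Problem sizes: the default cohort (60 lesions, 2 400 feature rows)
completes in roughly a minute on one CPU; the test suite uses a 6-lesion
session cohort for unit-level checks and one full default run for the
cohort-level assertions.

## Known limitations

* The level set is a desk-scale morphological implementation; very small
  (< ~12 voxel) or very low-contrast lesions may under- or over-segment,
  and such failures are reported as exclusions rather than hidden.
* The STAPLE specificity estimate depends on the bounding-box margin; the
  5-voxel default is appropriate for lesion-scale crops, not whole-body
  grids.
* Cohort-level percentages (fractions of highly robust features) are
  properties of the synthetic conditions; only their directions — the
  gain from thresholding, the penalty of relative resampling, the
  volume dominance of TLSRE — are expected to transfer to real cohorts.
* NIfTI I/O assumes axis-aligned affines; oblique orientations are out of
  scope.
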