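# Methods

This note documents the models, algorithms and numerical choices behind
`radrepeat`, in the order the pipeline runs them.

## Image perturbation

A perturbation is the composition of a rigid transform and a contour
randomization, applied to an image/segmentation pair to emulate a
repeat scan.

**Rigid transform.** Rotation about the axial (z) axis through the mask
bounding-box centre, by an angle drawn uniformly from a configurable
grid (default {−5°, 0°, 5°}), followed by a translation whose per-axis
magnitude is drawn uniformly from a grid (default {0, 0.2, 0.4, 0.6,
0.8} px) with an independent random sign per axis. The joint
distribution of "random combinations" is not uniquely determined by a
parameter table alone; per-axis magnitude × independent sign with a
single shared angle is the least-assumption choice and is configurable.
Images are resampled with cubic B-spline interpolation, masks with
linear interpolation re-binarized at the 0.5 partial-volume threshold;
out-of-field voxels take value 0. An identity spec short-circuits to a
bit-exact copy so that zero-perturbation configurations are exact
no-ops.

**Contour randomization.** A random displacement field is built in four
steps: (1) i.i.d. uniform(−1, 1) per voxel per component; (2) the
z-component of all voxels in an axial slice is replaced by one shared
uniform(−1, 1) draw per slice, emulating the uniform through-slice
variation of slice-by-slice manual contouring; (3) each component is
divided by its RMS over the grid and multiplied by a physical intensity
(default 1 mm per dimension); (4) each component is smoothed by a
Gaussian with physical sigma (default 10 mm). Because the smoothing
weights are identical for all in-plane positions, step (4) preserves
the slice-constancy of the z-component exactly. Note that normalization
precedes smoothing, so the *realized* post-smoothing RMS is much
smaller than the nominal intensity — smoothing strongly attenuates
white noise. The mask is backward-warped through the field with linear
interpolation and re-thresholded at 0.5. Order of operations: rigid
first, then contour randomization of the rigidly transformed mask.

## Preprocessing and feature extraction

Images and masks are resampled to 1 mm isotropic spacing with aligned
grid origins (cubic spline for images via a not-a-knot tensor-product
interpolant, which is exact on linear ramps and free of boundary
ringing; linear + 0.5 threshold for masks). The filter bank comprises
the identity, 3D Laplacian-of-Gaussian responses at physical scales
1–5 mm (implemented as Gaussian smoothing followed by the discrete
Laplacian and scaled by σ², so constants map to exactly zero), and the
eight single-level undecimated coiflet-1 wavelet decompositions
(separable periodic convolutions; outputs stay on the input grid, which
ROI-based extraction requires). "Coiflet-1" resolves an ambiguous
filter-name spelling; no wavelet family with the literal printed name
exists.

Each filtered image is discretized inside the ROI to a fixed bin number
(default 32) with bin width (max − min)/N computed over ROI voxels and
the maximum assigned to the top bin; discretization is per (image,
mask) instance, after filtering.

Features follow IBSI definitions with the reference-extractor class
sizes: 14 shape, 18 first-order, and 75 texture features (GLCM 24,
GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5), for a registry of
14 + 14 × 93 = 1316 with the default bank. Conventions that IBSI leaves
open: GLCM is symmetric, distance 1, with features computed per
direction (13 unique 26-connectivity directions) and averaged; GLRLM
likewise; GLSZM zones are 26-connected; GLDM uses dependence threshold
α = 0 and distance 1, with dependence size counting the centre voxel
plus its equal-level in-ROI neighbours; NGTDM neighbourhood averages
use in-ROI neighbours only. Formulas use the actual gray-level values
(no compaction), and the normalized inverse-difference features use the
number of levels present. The GLCM set excludes the redundant
sum-average. Kurtosis is reported non-excess. Shape features come from
a marching-cubes mesh of the mask; the binary volume is pre-smoothed
with a 0.6-voxel Gaussian before meshing, which removes the staircase
inflation of surface area (a raw binary mesh biases sphericity of a
10 mm digital ball to 0.91; with regularization the ball measures
sphericity 0.976 and mesh volume within 2% of 4/3·π·r³). Axis lengths
are 4√λ from the PCA of physical voxel coordinates.

Every texture class has an independent brute-force enumeration oracle
in the test suite (explicit pair/run/zone/dependence loops) that the
vectorized implementation must match to 1e-9 on random volumes.

## Repeatability (ICC)

Feature and prediction repeatability use the one-way random-effects,
absolute-agreement, single-rater ICC,

    ICC(1) = (MS_R − MS_W) / (MS_R + (k − 1)·MS_W),

on balanced subjects × repeats panels (k = number of perturbations, or
2 for test–retest). The 95% CI follows the McGraw–Wong construction
from F = MS_R/MS_W with (n − 1, n(k − 1)) degrees of freedom. A
`k_plus_1_denominator` switch replaces (k − 1) with (k + 1) for
audit purposes; the standard form is the default because the (k + 1)
variant is inconsistent with the McGraw–Wong family that defines the
CI. Zero-variance panels make the ICC undefined; they are flagged
degenerate and treated downstream as non-repeatable (a constant feature
carries no predictive signal). Subjects missing repeats are dropped
with a logged count, never imputed.

Filters: volume dependence removes features with |Pearson r| > 0.6
against mesh volume on the unperturbed training table (absolute r —
dependence is about association strength, and anti-correlated features
are equally confounded); the repeatability filter retains ICC ≥
threshold; the univariate screen is the two-sided point-biserial
(Pearson) test, the natural choice for a continuous feature against a
binary endpoint.

## Modelling

mRMR ranking uses the mutual-information difference (MID) criterion:
first pick argmax I(f; y), then argmax I(f; y) − mean I(f; s) over
selected s; MIQ is available as an option. MI is estimated after
discretizing each feature into 3 levels at mean ± SD — a coarse but
stable quantization at radiomic sample sizes. Exact score ties break
lexicographically for determinism. The top 5 features feed an
easy-ensemble: each of n_ensemble rounds (default 500) trains one
member of the chosen family (logistic regression, RBF-SVM with Platt
probabilities, random forest, Gaussian naive Bayes — library defaults,
recorded in the run manifest) on all minority-class samples plus an
equal-size without-replacement majority down-sample; "down-sampled by
N times" is read as N rounds, matching the easy-ensemble family.
Features are z-scored with training-set statistics before any member
fit (needed for LR/SVM conditioning). Prediction is the arithmetic
mean of member probabilities. Both stages are scikit-learn estimators
(`MRMRSelector`, `EasyEnsembleClassifier`) and compose with sklearn
pipelines.

## Reliability evaluation

AUC uses the Mann–Whitney rank formulation with midranks (cross-checked
in tests against pair enumeration and sklearn's trapezoidal ROC). 95%
CIs come from subject-level bootstrap percentiles (default 1000
iterations); resamples that lose an outcome class are redrawn so the
iteration count stays fixed. Two models on the same subjects are
compared with a paired permutation test: the statistic is
AUC(a) − AUC(b), the null swaps each subject's (a, b) score pair with
probability 1/2, and the p-value uses +1 smoothing. Swapping model
assignments rather than outcome labels keeps the marginal score
distributions intact and is the appropriate null for "same
discrimination". Prediction ICC builds a balanced panel of ensemble
probabilities over perturbed (k = n_perturbations) or retest (k = 2)
inputs and delegates to the ICC estimator. Dice and Hausdorff (boundary
voxels, physical mm, symmetric max-min via KD-trees) quantify
segmentation similarity.

The end-to-end sweep trains one model per (repeatability source ×
threshold × classifier) cell, skipping cells whose threshold leaves
fewer candidates than the selection size — with a logged reason, since
that event itself is informative (at high thresholds the test-retest
source routinely retains too few features).

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes,
not the physics of any modality. Per subject: an ellipsoid (radius
6–10 mm, per-axis anisotropy ±20%, jittered centre) whose boundary is
deformed by the same contour-randomization operator used for
perturbation, with subject-specific intensity up to 2 mm — boundary
irregularity is the first latent. Inside, intensity is a 50-unit
plateau (edge-softened by a 1 mm Gaussian envelope) plus a 1.5
mm-correlated Gaussian random field scaled by a subject-specific
amplitude around 15 units — texture amplitude is the second latent.
Additive white noise (SD 2) completes the image. The binary outcome is
Bernoulli with logit = b₀ + effect_size · (z_texture + z_irregularity)/√2,
with b₀ solved so the mean probability equals the target prevalence
(default 0.3, a typical response rate for the kind of endpoint
modelled); effect_size defaults to 2. Retest pairs re-noise the clean
image, shift it rigidly by 1 mm in a random in-plane direction, and
redraw the segmentation with an independent contour randomization at
sigma 5 mm / intensity 20 mm — tuned once so the mean test-retest Dice
falls in 0.55–0.65 at n = 60, substantially below the ≈ 0.9
perturbation-level overlap, reproducing the situation where retest
variation is dominated by segmentation differences. The large nominal
intensity reflects the strong attenuation of the pre-normalized field
by smoothing (see above).

What the generator does *not* emulate: scanner/protocol effects,
DWI/ADC physics, intensity non-uniformity, multi-reader contouring
styles, or inter-site heterogeneity. Passing tests therefore
demonstrate the pipeline's internal correctness and the qualitative
repeatability-reliability mechanism, not clinical-data effect sizes.

## Problem sizes and defaults

The standard study conditions used by the test suite and the
acceptance script: 60 subjects on 32³ grids at 1 mm spacing, 10
perturbations per subject, thresholds {0, 0.5, 0.9},
logistic-regression ensembles with 50 rounds, 200 bootstrap and
permutation iterations. These are scaled-down conditions chosen so a
full sweep (≈ 730 extractions of 1316 features plus modelling) runs in
about four minutes on one CPU; the end-to-end trend checks use a fixed
panel of three cohort replicates (generator seeds 1, 3, 11) and
compare panel means, because a single 24-subject test split carries
several points of AUC noise. ICC calibration simulations use the
design-matched sizes n = 100, k = 40.

## Known limitations

- Feature values follow IBSI definitions but are not bit-compatible
  with any specific external extractor; where IBSI permits aggregation
  variants the package pins one convention (documented above).
- The mesh regularization sigma (0.6 voxel) trades a small systematic
  volume underestimate (≈ −2% for a 10 mm ball) for unbiased surface
  area; very small ROIs (< 5 voxel radius) are measurably shrunk.
- Rigid "registration" before retest Dice/Hausdorff is not implemented
  as an optimization: the synthetic retest images are generated with a
  known shift, and the segmentation-similarity levels are reported on
  the common grid.
- The permutation test assumes exchangeability of the two models'
  scores within subject under the null; it compares discrimination
  only, not calibration.
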