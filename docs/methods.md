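# Methods

This note documents the models, conventions, parameters and design choices
behind `matdecode`, and what the synthetic-data tests do and do not show.

## Steerable pyramid

The decomposition is built in the frequency domain with polar-separable
filters: raised-cosine radial windows with one-octave transitions and
`cos^(K-1)` angular windows for K orientations, normalized so the squared
filters tile the plane (`sum_k c^2 cos^(2(K-1)) = 1` with
`c^2 = 4^(K-1) / (K * binom(2(K-1), K-1))`).  Subbands are analytic: the
angular mask is restricted to one Fourier half-plane and doubled, so a
coefficient's magnitude is the local envelope and its real part is the
real-pyramid coefficient.  Orientation band 1 is centered on the vertical
frequency axis and therefore responds to horizontal image structure; band
k is rotated by `pi*(k-1)/K`.

**Downsampling is unitary**: at each scale the lowpass spectrum is cropped
to the central half and divided by 2.  Consequences, all exercised by
tests:

* exact Parseval identity,
  `sum(img^2) = sum(high^2) + sum_k |band_k|^2/2 + sum(low^2)`,
  with no per-scale weights (the factor 1/2 converts analytic-band energy
  to real-band energy);
* white noise has equal expected mean energy at every scale ("scale-flat");
* the lowpass residual of a constant image carries `2^n_scales` times the
  image mean.  The common alternative conventions (amplitude-preserving or
  no renormalization) trade these properties differently; the unitary one
  makes energy bookkeeping exact.

Scale s peaks at `pi/2^s` rad/sample = `2^-(s+1)` cycles/pixel; cycles per
degree follow from the viewing geometry (pixels per degree), which is a
parameter rather than a constant because display geometry varies between
experiments.  Consecutive scales are exactly one octave apart.

Preconditions: image dimensions divisible by `2^n_scales`; images should be
center-cropped (not resized) to meet this, avoiding resampling artifacts in
the spectra.

## Image-statistic families

* **pixel** (6): mean, variance (population normalization), skewness,
  kurtosis (non-excess, Gaussian → 3 — the texture-model convention),
  minimum, maximum.  Degenerate zero-variance images get skew 0 /
  kurtosis 3 by convention with a logged warning, keeping feature matrices
  complete; downstream z-scoring drops constant columns anyway.
* **spectral** (74): mean squared coefficient magnitude per subband of a
  6-scale / 12-orientation pyramid, scale-major ordering, plus highpass and
  lowpass residual energies.
* **filter** (877): texture-model statistics of a 4-scale / 4-orientation
  pyramid.  Composition under the shipped defaults (neighborhood 7 for raw
  lowpass autocorrelations, 9 for magnitude autocorrelations, both
  symmetry-deduplicated — the autocovariance is centrally symmetric, so
  only `(na^2+1)/2` central samples are unique):

  | block | count |
  |---|---|
  | pixel statistics | 6 |
  | skew+kurtosis of the 5 lowpass levels | 10 |
  | lowpass autocovariance, 7×7 dedup × 5 levels | 125 |
  | magnitude autocovariance, 9×9 dedup × 16 bands | 656 |
  | magnitude means (16 bands + 2 residuals) | 18 |
  | cross-orientation magnitude covariances (6 pairs × 4 scales) | 24 |
  | same-orientation parent magnitude covariance (4 × 3) | 12 |
  | phase statistics: Re/Im of coefficient × phase-doubled parent (8 × 3) | 24 |
  | highpass + lowpass residual variances | 2 |
  | **total** | **877** |

  The classic texture model pins the statistic *families* but not one
  canonical parameter count; published analyses report totals that depend
  on neighborhood sizes and deduplication choices.  The configuration
  above is the package's documented default; `matdecode features
  --explain` prints it, and the count derivation is pure arithmetic in
  `filter_statistics_breakdown`.  Cross-scale blocks use the
  same-orientation parent (upsampled by Fourier zero-padding); phase
  statistics are mean products of the child's real part with the real and
  imaginary parts of the phase-doubled parent.  All correlation-type
  entries are covariances of demeaned magnitudes (not Pearson r), so
  constant images yield zeros rather than 0/0.

## Grouping

Mean ratings over raters; the lowest and highest `round(n*fraction)` images
(round-half-away-from-zero: 84 × 0.25 → 21) form the groups.  Boundary ties
break by a stable sort on image id — determinism is required for testing
and the choice is otherwise arbitrary.  Cutoffs are recorded as the
fraction/(1-fraction) quantiles of the means.

## Classification

`DiagLinearClassifier` fits class means and a pooled diagonal covariance
(denominator n−2) with empirical priors; prediction is the prior-weighted
diagonal-Gaussian likelihood argmax, exact ties resolving to the first
class in sorted label order.  A variance floor of 1e-12 (on the
standardized scale) guards near-constant features.

Standardization is fit inside each training fold by default (no leakage);
`zscore="global"` reproduces analyses that z-score the full matrix before
cross-validating.  Because the discriminant depends on features only
through `(x-mu)^2/sigma^2`, predictions and posteriors are invariant to
per-feature affine maps, so the two modes give identical labels — both are
provided for methodological fidelity, and the equivalence is asserted in
the tests.  The vectorized LOO path computes all folds with rank-one
updates and is tested equal (labels and posteriors) to an explicit
standardize–fit–predict loop per fold.

Permutation nulls shuffle labels without replacement (preserving group
balance) and take the empirical (1−alpha) quantile of null LOO accuracies
as the threshold.  Leave-one-out accuracy on null data is slightly
*pessimistic* at small n (holding out an observation shifts its own class
mean away); at the 42-fold design size the bias is negligible, and the
permutation threshold is computed with the same procedure, so inference is
unaffected either way.

## Neurodecoding

ROI decoding vectorizes each beta volume over in-mask voxels (C-order
linear index).  The searchlight measures its sphere radius in voxel units
(a `radius_mm` option converts via the affine); sphere members outside the
gray-matter mask or the volume are dropped, not zero-filled, to avoid
injecting constant features.  Chance (0.5 for balanced two-class designs)
is subtracted for the group map.  The second level is a voxelwise
one-sample, one-tailed t across participants (df = n−1) thresholded at the
critical t for the chosen alpha; suprathreshold voxels form
26-connectivity clusters, and clusters with more than `cluster_k` voxels
are tabulated with peak voxel/mm coordinates.  Inputs are assumed
spatially normalized to a common grid; normalization itself is out of
scope.

## Agreement statistic

For one pole with group size n, classifier A labeling a and classifier B
labeling b images as members, independence predicts agreement
`E = (a/n)(b/n) + (1-a/n)(1-b/n)`.  a and b may be real-valued
(participant-averaged counts).  Each pole is analyzed separately per
participant; significance is a paired one-tailed t across participants of
(actual − expected), with a pooled statistic averaging the two poles per
participant.  Note E is linear in b, so over b its minimum lies at an
endpoint (b=n for a<n/2, b=0 for a>n/2).  A t test was chosen over a
nonparametric alternative because the per-participant differences are the
natural paired unit and participant counts are small.

## Synthetic data

The generator emulates the statistical skeleton of a material-perception
study: 84 images, 6 raters, 3 properties, 15 participants, one beta map
per stimulus.

* **Textures**: Gaussian noise shaped to `f^(-alpha)` with alpha ~ U(0.5,
  2.5) per image and orientation gain `1 + a*cos(2(theta-theta0))`,
  a ~ U(0, 0.6); normalized to mean 0.5, SD 0.15, clipped to [0, 1].
  Spectral slope is the roughness-like dimension; anisotropy adds
  orientation variety.
* **Ratings**: a coupled property maps the rank of its driving statistic
  onto a latent 1..7 score, adds an image-level N(0, 1.5) idiosyncrasy
  (the part of a percept no image statistic explains — without it both
  classifiers sit at ceiling and the agreement statistic degenerates,
  since a=n forces actual ≡ expected), then per-rater N(0, 0.75), rounds
  and clips.  The null property draws its latents independently.  Driving
  statistics (high-frequency power fraction, RMS contrast, mean luminance)
  are computed by direct FFT, deliberately sharing no code with the
  steerable pyramid the pipeline uses.
* **Betas**: a contiguous blob of 30 voxels (nearest-to-center inside a
  radius-4 ROI sphere at the gray-matter centroid) carries
  `0.25 * w . x_i` with participant-specific standard-normal weights w
  over the z-scored driving statistics, plus N(0, 1) noise in every
  gray-matter voxel; voxels outside gray matter are zero.  The amplitude
  places ROI decoding accuracy in the 0.6–0.8 range and the image
  classifier near 0.9 — the intermediate regime a real study reports, and
  the only regime in which the agreement analysis is informative.
  `beta_signal="group"` substitutes the group indicator (the separable
  sanity case) and `"none"` gives pure noise.

What the generator does **not** emulate: photographic structure (edges,
specularities, shading), rater response styles, spatial autocorrelation of
fMRI noise, hemodynamics (betas are generated directly; GLM estimation is
an upstream input), or anatomical variability (participants share a grid
by construction).  Passing tests therefore demonstrate that the *analysis
chain* recovers planted structure under its own assumptions — not that
real materials or real BOLD data behave this way.

## Problem sizes used in tests

The unit suite runs on 24–32 images at 128² pixels, 3–4 participants and
~16³ volumes.  The parameter-recovery acceptance tests keep every
statistical condition at the defaults (84 images at 256², 21-image groups,
500 permutations, 15 participants, default noise levels) and reduce only
the voxel grid (24×28×24) and the number of participants entering the
searchlight stage (6); the ROI/blob geometry and per-voxel signal
statistics are unchanged by either reduction.  The pipeline's full default
grid (40×48×40) is used when invoked directly.

## Known limitations

* The filter-statistics composition is one documented configuration among
  the family the texture model defines; totals differ between published
  analyses and no single canonical count exists.
* The searchlight loops over centers in Python with vectorized inner
  algebra; at full 40×48×40 grids with 15 participants it is minutes, not
  seconds.
* Likert discretization creates rating ties, so rank correlations with a
  driving statistic cannot reach exactly 1 even at zero noise.
* `radius_mm` requires isotropic voxels; anisotropic geometries fall back
  to voxel-unit spheres.
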