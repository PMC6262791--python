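# Methods

## Nuclear counting model

The counting pipeline assumes one intensity peak per nucleus: nuclei are
bright blobs on a dark background, roughly Gaussian in profile, sampled on
an anisotropic voxel grid (in-plane pixel size dx, z-step dz, with
dz/dx ≈ 3 at the default spacing of 0.692 and 2.1 µm). No point-spread
function or depth attenuation is modeled; the algorithm only requires a
single local maximum per nucleus after smoothing.

Processing order: Hi-Lo linear rescaling → anisotropic Gaussian smoothing →
gray-level threshold L → h-maxima → connected components → centroids.

- **Hi-Lo rescaling** maps a chosen background level to 0 and a ceiling to
  one gray level below the bit-depth maximum (254 for 8-bit), clipping at
  both ends and flooring to integers. This standardizes stacks acquired at
  different gains before the fixed thresholds L and h are applied.
- **Smoothing** uses per-axis standard deviations (σ_xy, σ_xy, σ_z) in
  voxel units with σ_z = σ_xy·(dx/dz), recomputed from the grid it is
  applied to, so the physical smoothing scale is isotropic. σ_xy is
  specified in xy-voxel units. Boundary handling is reflection, which
  conserves total intensity; this choice is fixed for reproducibility.
- **Threshold L** is applied after smoothing. The alternative order
  (threshold the raw data, then smooth) is defensible; applying L
  post-filter keeps the filter linear on the raw data and makes L directly
  comparable to the smoothed peak heights. The choice matters only near
  L and is documented here because it is switchable in principle: to
  emulate the other order, rescale with `background=L` first.
- **"Regional maxima with minimum height h"** is implemented as the
  extended-maxima transform: grayscale reconstruction by dilation of
  (image − h) under the image, followed by regional-maxima extraction.
  This is the standard morphological reading of "minimum height"
  (MATLAB's `imextendedmax`, scikit-image's `h_maxima` family). A
  connected equal-valued plateau is one maxima region regardless of size —
  no peak splitting.
- **Connectivity** defaults to 26 (full 3D neighborhood); 6 and 18 are
  accepted. The full neighborhood merges diagonal plateaus and so reduces
  double counting of single nuclei.
- **Centroids** are unweighted means of component voxel coordinates
  (region centroids, not intensity-weighted), converted to µm. ROI
  restriction assigns each centroid to its nearest voxel.

σ_xy, L and h have no universal values: on real data they are tuned by
overlaying detected centroids on intensity isosurfaces and stepping through
cross-sections. The package treats them as required configuration. For the
default synthetic scene (nuclear σ = 1.8 µm, amplitudes 160-230,
noise_sd ≤ 10), σ_xy = 2 voxels, L = 20, h = 30 recovers planted counts
with ≥ 98% recall and precision.

Degenerate inputs: a stack that is empty after thresholding yields an empty
result (not an error); h at or above the post-threshold dynamic range
yields an empty result with a warning.

## Fate-map fractions

The green (unconverted) fraction needs a total-nucleus count. With a
dedicated counterstain channel, the total is counted there directly. In the
standard two-channel photoconversion scheme the total is the green/red
union: n_green + n_red minus double positives, where a green centroid
within a matching radius of a red centroid is taken to be one partially
converted nucleus. The radius defaults to 3 µm — a typical nuclear radius
at this imaging scale — and is configurable; how double positives were
handled in manual counts is generally unstated, so the rule is explicit
and tunable here.

## Trajectory metrics

Tracks are ordered (t, x, y, z) samples at uniform Δt (2.75 min between
z-stacks for the default time-lapse setting). Average speed is defined as
path length / elapsed time, which equals the mean of framewise speeds under
uniform Δt — the two readings of "average speed" coincide, so the choice is
immaterial for gap-free tracks. Tracks with gaps are rejected rather than
interpolated (manual tracking is gap-free by construction; interpolation
would silently shorten paths). The overlap QC normalizes the intersection
by the smaller mask — the permissive reading appropriate for an acceptance
check on manual tracking — with the 50% threshold configurable.

## Morphometry conventions

- Roundness is the Fiji shape descriptor 4·Area/(π·major²), with the major
  axis from the moment-fitted ellipse (full axis = 4·√λ_max of the
  coordinate covariance). Values are clipped at 1.0, which rasterized
  near-circles can slightly exceed. Regions under 5 px or collinear are
  rejected.
- Elongation angles are axial (a cell has no head): angles are folded into
  [−90°, 90°), measured in image coordinates (y down) against a supplied
  AP-axis vector. With AP-aligned wild-type cells near 0°, variances of
  folded angles are well-posed for F-test comparisons; near-circular
  regions (roundness ≥ 0.95) return a flagged, unstable angle. Circular
  statistics would be the alternative for broadly dispersed angles.
- The quarter-intensity profile averages across the rectangle width per
  row, splits rows into four quarters of floor(n/4) rows with remainder
  rows assigned to the middle (the outer quarters drive the statistic and
  must be equal-sized), and reports anterior/posterior mean ratio. The
  image must be pre-rotated so the vesicle runs vertically, anterior at low
  row index. A zero posterior mean yields a flagged undefined ratio.
- Volumes are voxel counts × dx²·dz per label; relative shares divide by
  total nonbackground volume.
- The fissure opening angle is computed from three user-supplied points
  (lens-center vertex, one point per fissure margin) on a pre-oriented
  lateral view; no automatic lens detection is attempted.

## Statistics conventions

All tests are two-sided. Student's t uses the pooled variance with
df = n_a + n_b − 2; Welch's t uses the Welch-Satterthwaite df. The F-test
reports F = s_a²/s_b² with p = 2·min(P(F ≤ f), P(F ≥ f)) capped at 1.
Fisher's exact test uses the probability-mass rule (sum over tables with
the same margins whose probability does not exceed the observed table's) —
the convention of mainstream statistics libraries. Box summaries use
type-7 (linearly interpolated) quartiles as hinges, matching ggplot2's
defaults, whiskers at the most extreme attained values within 1.5·IQR of
the hinges, and list the rest as outliers. For tiny skewed samples an
interpolated hinge can lie beyond the attained whisker; the whiskers are
kept at data values, as ggplot2 draws them. Group summaries report the
sample s.d. (n−1 denominator) and flag n = 1 groups explicitly, since "±"
values are often ambiguous between s.d. and s.e.m.

## Synthetic data: what it does and does not emulate

The generators produce: anisotropic two-channel 8-bit stacks of isotropic
Gaussian nuclei with additive clipped Gaussian noise; rotated-ellipse cell
masks with known roundness and orientation; constant-speed polyline
trajectories with seeded positional jitter; and disjoint labeled volumes
with exact physical volumes. Defaults mirror the acquisition they stand in
for: 512×512 planes (tests use smaller crops), (0.692, 2.1) µm spacing,
2.75 min frame interval, nuclei ~5-10 px across in xy (σ = 1.8 µm — a
fixture choice consistent with 40× imaging, not a measured value).

Deliberately not modeled: PSF anisotropy, depth-dependent attenuation,
Poisson photon statistics (the Hi-Lo preprocessing normalizes background
anyway), bleed-through between channels, nuclear shape variation, cell
division, and tissue mechanics. Passing ground-truth recovery on these
scenes therefore demonstrates the correctness of the measurement chain —
detection, geometry, bookkeeping — not robustness to every confound of real
confocal data; on real stacks the σ_xy/L/h tuning step absorbs much of that
gap.

Sampling note: constant-speed polyline sampling only lands exactly on
interior waypoints when the corner arclength is a multiple of the sampling
increment; otherwise a chord cuts the corner and the sampled path is
marginally shorter than the waypoint polyline. Exactness tests construct
commensurate segment lengths.

## Problem sizes

Validation runs at desk scale: ground-truth recovery uses 50 nuclei in a
40×192×192 stack (noise_sd 5) and 120 nuclei in 48×256×256 (noise_sd 10);
oracle equivalence uses 200 random grids up to 12×12×6 at connectivities 6
and 26; calibration uses 10,000 null t-test replicates (n = 10 per group)
and 500 F-test replicates at n = (49, 35) with a ninefold variance ratio.
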