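# Methods

This note records the model underlying each pipeline stage, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic phantom does and does not establish about
real data.

## Coordinate and unit conventions

Arrays are indexed `[ix, iy, iz]` with x = left-right, y =
anterior-posterior, z = inferior-superior; voxel indices are 0-based and
voxel-centred (voxel `(i, j, k)` sits at `(i·dx, j·dy, k·dz)` mm);
intervals are half-open. Lengths are mm, areas cm², volumes cm³,
densities mg/cm³ equivalent aqueous K2HPO4 (which can legitimately be
negative in fat-rich tissue), areal BMD g/cm². The mg→g conversion is a
fixed factor of 1000. The default acquisition lattice is 0.781 mm in-plane
with contiguous 3 mm axial slices (a 40 cm display field of view on a 512
grid).

## Calibration

The HU→density map is an unweighted ordinary least-squares line through
(mean rod HU, nominal rod density) points. Rod means are taken over a disk
eroded to 0.7 of the nominal rod radius, averaged across the slices where
the rods are visible; the erosion keeps partial-volume rims out of the
average. Both choices are this package's own: the number of rods a vendor
fit uses, any weighting, and the rod-ROI rule are not public. Beam
hardening is modelled as a single multiplicative correction to the slope,
estimated from the 200.0 mg/cm³ QA reference as nominal/measured; it is
reported by the QA check but applied only when the caller opts in, so a QA
failure is visible rather than silently absorbed. The QA pass tolerance
defaults to ±2% and is configurable.

## Segmentation

Three parameters control the adaptive algorithm: a floor below which a
voxel can never be bone (−250 mg/cm³), the neighbourhood width used to
adapt the local threshold (5 voxels, a cube in voxel units, 3D), and a
seed threshold (120 mg/cm³). The published description names these
parameters but not the update rule, so the rule here is the simplest one
consistent with all three: voxels above the seed threshold are tentative
bone; a refinement sweep then re-labels every voxel within the
neighbourhood cube of current bone as bone iff its density reaches the
mean density of that cube (and exceeds the floor), repeating until stable
(at most 50 sweeps). Mostly-background partial-volume voxels fall below
the local mean and are pruned; mostly-bone voxels are admitted. Two
rejected variants are worth recording: comparing with `>=` against the
local mean over the whole grid classifies any uniform region above the
floor as bone (a constant field equals its own local mean), and a strict
`>` comparison is numerically fragile in constant regions where density
and local mean differ only by float rounding. Restricting refinement to
the neighbourhood of existing labels removes both failure modes without
adding a parameter.

The cortical envelope is closed by per-axial-slice 2D hole filling
followed by 3D hole filling — the 2D pass guarantees closure on strongly
anisotropic grids where a marrow cavity can stay 3D-connected to the
outside between 3 mm slices — and the largest 26-connected component
intersecting the user's analysis box is retained (ties break toward the
box centre). Inside the envelope no marrow/bone distinction is made.
Component selection means the envelope-fill step is a superset operator on
single-component masks only; disconnected debris is deliberately dropped.

## Orientation

Standard pose: shaft vertical, femoral head on the +x side, neck axis in
the coronal plane. The shaft axis is estimated from the distal (lowest-z)
40% of the mask, one point per axial slice: the centroid of the
near-maximal plateau of the slice's inscribed-disk radius map, a centre
estimate the trochanteric prominences cannot shift, followed by a
principal-axis fit through those centres. The head centre is the centre of
the largest inscribed sphere in the proximal mask (3D distance transform
argmax). The neck axis is the principal axis of the head+neck assembly —
proximal voxels lying radially outside the estimated shaft cylinder —
which is symmetric about the anatomical neck axis, so its first principal
axis is unbiased in direction even though the head dominates the mass.
Only the component of the neck axis orthogonal to the shaft matters for
the pose (it is mapped to +x), so a bias in the estimated neck *elevation*
does not propagate into the rotation. Degenerate geometry (near-isotropic
principal axes, no mass outside the shaft) raises an orientation error so
the operator can supply manual angles; automatic left/right detection is
out of scope (a mirror flag covers right femurs).

Resampling is trilinear onto an isotropic grid at the in-plane spacing
(0.781 mm default), which makes the projected pixel area well-defined.
Masked density and mask occupancy are interpolated separately; an output
voxel is bone when occupancy ≥ 0.5 and its density is the
occupancy-normalised interpolated density, which keeps boundary voxels at
interior-like values. Voxels outside the mask carry NaN, never zero — zero
is a valid equivalent density. Total mass is conserved to about 0.5% on
the reference phantom (tested bound 1%, round trip 2%).

## Projection and ROI measurement

The projection is a parallel-beam column sum along +y on the oriented
lattice: per pixel, mass = Σ ρ·voxel-volume/1000 and bone path volume =
count·voxel-volume over the mask. Because the pixel lattice equals the
voxel lattice, mass conservation is exact (float-sum exact, verified at
1e-12 relative) and background pixels are exactly zero.

ROI geometry on the projection: the head is the largest circle inscribed
in the medial lobe of the silhouette; the neck axis is the line from the
head centre through the bottleneck of the widest path (maximum minimal
clearance, 8-connected Dijkstra with a path-length tie-break) from head to
distal shaft — both endpoints of that line straddle the anatomical axis —
and the neck box centre is the middle of the plateau of near-minimal
silhouette cuts along the axis. The box defaults to 15 mm along the axis
and spans the full neck (minimal cut + 6 mm). The inferior boundary of the
Intertrochanter ROI sits where the medial silhouette edge rejoins the
straight shaft below the lesser-trochanter prominence (edge within 0.5 mm
of the distal-shaft reference after a 3-pixel smoothing; fallback to 25%
of the span above the silhouette bottom if no prominence is found). The
trochanter/intertrochanter border is the horizontal line through the neck
box's most inferior corner. All of these geometric rules are this
package's own deterministic constructions — the published description
names the ROIs but no formulas — and every parameter is an explicit,
operator-adjustable argument; manual placement via
`HipROISet.from_geometry` is first-class. The neck's lateral margins come
from the background-free silhouette itself, not from a
percent-of-maximum profile rule, which is only needed when a noisy
soft-tissue background must be suppressed.

Because the visible 2D neck corridor is bounded by the head on one side
and the greater-trochanter silhouette overlap on the other, its midpoint
sits systematically distal of the 3D neck midpoint; recovery tests
therefore check the detected axis direction and the centre's perpendicular
distance to the generating axis, with the along-axis position treated as
the operator-adjustable quantity it is clinically.

Compartments: a voxel is cortical iff ρ ≥ 350 mg/cm³ (configurable),
trabecular otherwise; both compartment volumes are re-projected through
the same ROI labels, so per-ROI cortical + trabecular mass and volume
equal the integral values exactly by construction. A compartment's area is
its own projected silhouette within the ROI, so compartment aBMD refers to
the area that compartment actually covers.

## Densitometry statistics

Long-term precision: per-patient sample SD over 3–4 visits (n−1
denominator, no detrending), combined as the root of the unweighted mean
of variances across patients. Unweighted is the primary definition because
the estimate is described as an RMS of SD estimates with no
degrees-of-freedom weighting; a df-weighted variant is available behind a
flag. CV references the grand mean of patient means. The interobserver
comparison defaults to a paired two-tailed t-test (the same scans analysed
twice); unpaired Welch is a flag. Cross-device regression is OLS of the
reference device on the test device (DXA ~ CTXA) with Pearson r and
SEE = √(RSS/(n−2)). Welch's statistic uses Satterthwaite degrees of
freedom. Normality testing is the Anderson–Darling case-3 statistic
(mean and variance estimated) with the small-sample adjustment
A²* = A²(1 + 0.75/n + 2.25/n²) and 5% critical value 0.752. The
percent interobserver difference uses observer 1 as denominator (the
published values round identically under all three candidate
denominators). A `t_score` helper is exposed but no reference population
data ships with the package.

## Synthetic phantom

The digital femur is a constructive-solid-geometry union — vertical shaft
cylinder (radius 14 mm, open distal end), neck cylinder (radius 12 mm,
length 45 mm, neck-shaft angle 130°), head sphere (radius 21 mm), lesser-
and greater-trochanter spheres — wrapped in a 3 mm cortical shell at
800 mg/cm³ over a 150 mg/cm³ trabecular interior, in a 0 mg/cm³ water-like
background, next to a three-rod insert (0/100/200 mg/cm³). The greater
trochanter is included because without it the narrowest silhouette passage
is the neck-shaft junction notch rather than the neck, and no DXA-like
neck landmark exists. Rasterization averages a 3× supersampled sub-grid
per voxel so partial-volume behaviour at the cortex is realistic; HU is
the inverse of the generating calibration (slope 2.0 mg/cm³ per HU,
intercept −5) plus Gaussian HU noise (default SD 5 HU, a plausible
abdomen-protocol noise level; validation phantoms use 0). Everything is
deterministic per seed.

The oracle integrates the same analytic geometry along y on a fine
lattice (default 0.25 mm in-plane, 0.1 mm along y — an order of magnitude
finer than the acquisition grid) without touching any pipeline code, and
converges to 0.5% between successive resolutions. The longitudinal cohort
generator draws hierarchical normals (default 22 patients × 3 visits,
mean 0.647 g/cm², between-patient SD 0.08, within-patient SD 0.012, no
drift), emulating a stable osteoporotic precision cohort.

What the phantom does not emulate: trabecular texture, beam-hardening
streaks, scatter, metal, patient motion, anatomical shape variation, and
soft-tissue heterogeneity. Passing tests therefore demonstrate the
correctness of the geometry, calibration arithmetic, mass bookkeeping and
statistics — not clinical segmentation robustness on pathological
anatomy.

## Verified tolerances

On the zero-noise reference phantom at default spacing: segmented volume
within 5% of the analytic volume (measured ≈3%), total mass through
rotation conserved within 1% (≈0.6%), whole-silhouette and Total-Hip aBMD
within 5% of the oracle (≈4.3% and ≈4.7%; the residual is the partial-volume
rim where sub-half-occupancy voxels are excluded from the binary mask),
cortical mass fraction within 3 points absolute (≈2.0), pose recovery
within 0.5° for standard-pose input and 1° for rotated input. Statistical
calibrations: the RMS-precision estimator recovers a generating 0.012 g/cm²
within 5% over 500 cohorts; Welch's test holds its 5% level within
[0.04, 0.06] over 10,000 replicates. Problem sizes (phantom grid
136×92×42, oracle pitch 0.4/0.2 mm in routine runs) were chosen so the
whole suite and the acceptance script each complete in minutes on one CPU.

## Known limitations

Segmentation under-counts the sub-half-occupancy partial-volume rim, so
projected aBMD is biased a few percent low against the analytic truth at
3 mm slices; real systems face the same trade-off and the bias shrinks
with slice thickness. Automatic ROI placement assumes a connected,
roughly anatomical silhouette; it fails loudly (never silently) and manual
placement covers the rest. The beam-hardening model is a single scalar
slope factor; spectral physics, multi-energy calibration and
CaHAP↔K2HPO4 conversion are out of scope, as are T-score reference
databases, Ward's triangle, and structural (moment/strength) analysis.
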