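# Methods

This note documents the models, conventions and parameter choices behind
`spheromorph`, and what its synthetic validation does and does not show
about real micrographs.

## Conventions

Coordinates are 0-based `(row, col)` with pixel centers at integer
coordinates; pixels are square with side `pixel_size` μm. Foreground
connectivity is 4-connected; boundary tracing is 8-connected. Angles are
measured in radians from the +column axis toward the +row axis and reduced
to [0, π). The spheroid is assumed darker than its background (brightfield
convention); a polarity switch inverts.

## Phantom generator

Every stage is validated on phantoms: shapes with closed-form volumes —
sphere (V = 4/3·πr³), prolate ellipsoid of revolution about its major axis
(V = 4/3·πab²), two overlapping spheres (inclusion–exclusion with the
standard sphere–sphere lens term), and a body sphere with a bud centered on
its surface. Rasterization uses the pixel-center-in-region rule: a pixel
belongs to the truth mask iff its center lies inside the continuous
silhouette. The rendered appearance, on an 8-bit scale, is background 230,
body 110, core 60 (a concentric silhouette scaled by the core fraction,
default 0.5), a bright halo of +20 tapering linearly over 3 px just
outside the boundary, additive Gaussian noise of SD 6 and an optional
linear illumination gradient. These levels were chosen once to make
Otsu-style segmentation nontrivial (halo, core, noise) but reliable; real
brightfield appearance is not quantified anywhere we could calibrate
against, so they are plausibility defaults, exposed as parameters.

Plate fixtures emulate a one-spheroid-per-well 96-well plate. Defaults are
the study conditions the pipeline is meant for: 70% spherical phantoms
(the fraction of colonies that spheroidize within the first culture week),
the rest split evenly across ellipsoid, figure-8 and budding; volumes
lognormal around 0.112 mm³ (a typical selected-population center) with
σ_log = 0.3, since a diameter CV near 11% in a rotary-vessel population
translates to a volume CV of roughly 3× that. Each well derives an
independent RNG stream from `(plate seed, well index)`; identical
spec + seed is bit-identical.

Known non-realisms: no optics (defocus, diffraction, uneven halo), no
debris or touching spheroids, sharp two-level interior. Passing tests on
phantoms therefore demonstrate the geometry and statistics of the
pipeline, not robustness to acquisition artifacts.

## Segmentation

Min–max normalization → global Otsu threshold → dark side → closing with a
disk of radius 3 px → hole filling → drop components below 1% of the image
→ keep the largest 4-connected component. A guard rejects images whose
Otsu split separates classes by less than 0.3 of the normalized range
(pure-noise blanks split at ≈ 0.2, real body/background contrast at
≈ 0.6): such images yield "no object found" rather than a noise blob.
QC flags: `touches_border`, `multi_object` (second pre-cleaning component
≥ 25% of the largest), `too_small` (d_eq below 100 μm by default).

On noise-free convex phantoms segmentation reproduces the truth mask
exactly. The closing step fills a few pixels of strongly concave necks
(figure-8 waists) by design — exactness there is traded for robustness to
noise speckle; all shapes stay above Dice 0.95 at default noise.

## 2D morphometry

Area is the pixel count × pixel_size²; perimeter is the 4-direction
Crofton estimator. The choice matters: naive boundary-pixel counting
inflates P enough that a perfect digital disk would fail the SI ≥ 0.90
spherical cutoff, while the Crofton estimate keeps digital disks at
SI ≈ 0.99. SI = 4πA/P² is clipped at 1 to absorb discretization
overshoot. The feret axis is the maximum pairwise distance between
*pixel centers*, computed on the convex hull with ties broken toward the
smaller angle; a 100×50 px rectangle therefore measures √(99²+49²), not
the outer-corner diagonal. The direction sign is canonicalized before the
angle is computed so the result is bit-reproducible regardless of endpoint
ordering. The minimum caliper is the smallest hull width (rotating-calipers
construction). Intensity profiles are bilinearly sampled along a line
through the centroid (default direction: the feret angle), on a grid
symmetric about the centroid, clipped to the mask bounding box and
normalized to their maximum.

## Volume by solids of revolution

The estimator assumes local rotational symmetry about the feret axis:

1. **Decomposition.** A disk of radius 0.3 × (d_eq/2) px drives the split.
   Components of the *eroded* mask seed the parts; any component of the
   opening residual larger than 1% of the mask seeds a protuberance of its
   own (a bud the erosion removes entirely leaves no core). Every mask
   pixel is assigned to the nearest seed — pixels the opening covers only
   to eroded-core seeds, so a bud seed never captures a cap of the body —
   and parts below 1% are merged into their nearest neighbor. The parts
   tile the mask exactly. The erosion-component formulation is deliberate:
   a plain opening can never separate two overlapping lobes, because its
   dilation step reconnects the eroded cores through the overlap. The 0.3
   fraction clears realistic figure-8 necks (≈ 0.22–0.31 of the lobe
   radius, plus ~3 px of widening introduced by the segmentation closing)
   while leaving convex bodies whole; both thresholds are configurable.
2. **Revolution.** Each part is rotated (nearest-neighbor, a shared
   documented choice) so its feret axis lies along the columns; every
   maximal foreground run in a column sweeps a disk of the run's diameter
   centered at the run midpoint in the (row, z) plane. Centering each disk
   on the *chord midline* rather than the feret line itself makes the
   solid's z-projection reproduce the input silhouette — a tested
   invariant — and is our resolution of an ambiguity in the underlying
   method description; it is documented as a choice, not claimed as
   identical to other implementations. Multiple runs per slice get their
   own disks, preserving concavities.
3. **Connection.** Each neck is plugged by a conical frustum along the
   segment joining the two parts near the contact, end radii equal to the
   parts' local half-chords, radius linearly interpolated ("locally
   adapted" rendered as a linear taper), rasterized as perpendicular disks
   at ≤ 1 px axial spacing.
4. **Counting.** Voxels are counted once; volume = count × pixel_size³.
   Single-part solids are returned in the feret-aligned frame (their
   volume is frame-independent and exactly reproducible by a per-voxel
   brute-force oracle); multi-part solids are assembled in the image frame.

Accuracy on analytic phantoms: spheres and prolate ellipsoids within
0.5% at radii ≥ 30 px, figure-8 unions within 1.5%, buds within 0.5%.
Doubling pixel_size multiplies volume by exactly 8; in-plane rotation
changes disk/ellipse volumes by < 3%. An optional 2× supersampling flag
refines the grid for accuracy studies.

## Classification and selection

Classes are assigned in a fixed order: **spherical** iff SI ≥ 0.90 (the
only quantitative boundary inherited from the workflow); else **figure-8**
iff the second-largest decomposition part is ≥ 30% of the largest; else
**ellipsoidal** iff a single body with solidity ≥ 0.95 and aspect ratio
≥ 1.3; else **irregular**. The 30% / 0.95 / 1.3 thresholds are this
package's quantification of qualitative categories and are exposed as
parameters. One consequence of SI-first ordering: a small bud centered on
the body surface leaves SI at ≈ 0.92–0.94 (half the bud is hidden inside
the body), so such shapes classify as spherical even though the generator
labels their geometry "budding/irregular".

Selection keeps records that pass QC, have SI ≥ 0.90, and fall inside a
relative volume band (default ±15%) around a center (default: median of
the QC-passing volumes). The ±15% default reflects a typical selected
group with relative SD ≈ 12% (0.112 ± 0.013 mm³). Selection is idempotent
and, on lognormal populations, never increases the volume CV of the kept
subset. Plate tables round-trip through CSV at 6 significant digits.

## Assay statistics

Sample SD uses the n−1 denominator throughout; CV = 100·SD/mean is
reported to one decimal, matching how such tables are printed. Jarque–Bera
uses JB = n/6·(S² + (K−3)²/4) with biased sample moments against a χ²(2)
reference; Lilliefors uses the KS distance to a normal with estimated
parameters and a seeded Monte-Carlo p-value (the null distribution of the
statistic is parameter-free; default 10 000 standard-normal resamples,
add-one estimator). The unpaired two-tailed Student t-test (pooled
variance; Welch optional) is gated on both normality tests at α = 0.05 —
a failing gate refuses with an explicit override flag rather than falling
back to a nonparametric test, because the workflow it mirrors names no
fallback. Volume↔diameter uses d = (6V/π)^(1/3) (mm³ ↔ μm); nearest-50-μm
rounding is applied only when reproducing "approximately" printed category
diameters. "Deviance from linearity" is operationalized as the classical
replicate-design lack-of-fit F-test: F = (SS_lof/(k−2))/(SS_pe/(n−k))
against F(k−2, n−k), which is invariant to affine transforms of the
readout.

One power caveat found while validating: the Lilliefors test's power
against U(0,1) is only ≈ 0.54 at n = 100 (statsmodels' implementation
agrees); it reaches ≈ 0.95 at n = 200, which is where the suite tests it.

## Problem sizes and determinism

The validation suite runs phantom plates at 4.4 μm/px (a common CCD
calibration) with spheroids of 300–900 μm; the brute-force volume oracle
runs on 50 random blobs of ≤ 96 px (exact voxel-for-voxel agreement);
Monte-Carlo sizes are 10 000 replicates for Jarque–Bera size, 800 × 400
for Lilliefors size, and 2 000/500 replicates for lack-of-fit size/power
at the 5-category × 9-replicate design. All randomness flows from explicit
seeds; the phantom → measure → select chain is byte-reproducible.

## Known limitations

Single-view volume estimation is exact only for bodies rotationally
symmetric about an in-plane axis; silhouettes hide occluded concavities.
The neck-plug geometry (linear-taper frustum) is a stand-in for an
unspecified "locally adapted" connection. The segmentation recipe is a
documented Otsu+morphology baseline, not a re-implementation of any
specific tool's unpublished recipe. Phantoms do not emulate optical
artifacts, so field robustness must be established on real images.
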