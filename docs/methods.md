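# Methods

This note documents the models implemented in `urbantree`, the parameter
defaults and why they were chosen, the conventions that make the numerics
deterministic, and what the synthetic test scenes do and do not establish.

## Inventory model

A tree inventory is a set of points (one per stem) compared against a
reference database by distance. The pipeline assumes:

* a locally planar coordinate frame in meters (no CRS handling; inputs are
  expected in a projected system);
* normalized ALS heights (ground already removed; z = height above ground);
* flat ground for the street-level distance model (see below);
* building footprints available as polygons.

### Stage 1B: CHM and variable-window local maxima

`chm.rasterize_chm` grids the cloud at 0.25 m cells taking the per-cell
**maximum** height. Cells without returns become nodata, not zero: a
zero-filled street canyon would manufacture artificial height edges next to
crowns. `chm.smooth_chm` applies one pass of a window-mean filter (default
3×3) that averages only valid cells and shrinks at raster edges; nodata
stays nodata. The smoothing kernel is implemented as two box filters (sum
and count) so the nodata-aware mean is exact. `chm.clip_buildings` blanks
cells whose **center** lies inside or on a building polygon; cell-center
containment is the single point-in-polygon convention used everywhere
(deterministic, and exactly testable by enumeration).

`itd.detect_treetops` declares cell (i, j) with height *h* a treetop iff

1. *h* ≥ `min_height` (default 2 m);
2. no valid cell whose center lies within `win_a·h + win_b` meters (defaults
   0.12 and 0.5; optionally capped by `max_win_diameter`) is taller — the
   window always contains at least the queen (or rook) neighbors;
3. among equal-valued cells inside the window, (i, j) is first in row-major
   order (deterministic plateau rule).

The window is evaluated at the candidate's own smoothed height and its
output is treated as a circular **radius** in meters; both points are
conventions of the linear window-function family rather than physical
claims, so they are explicit here and configurable. Candidates carry the
smoothed CHM value as height and sit at cell centers.

### Stage 1A: street-level geolocation

Panorama stations know their position, heading, pitch, field of view and
image size. Two pixel-to-bearing models are provided: `equirect`
(panoramic: bearing offset linear in the column) and `perspective`
(rectilinear: offset = atan((2u/W−1)·tan(hfov/2))). Distance comes from the
stem-base row under a flat-ground model: the base sits below the horizon by
δ = −pitch + atan((2v/H−1)·tan(vfov/2)), and a camera `camera_height` (2.5 m
default, a typical capture-car mast) above ground sees it at
d = camera_height/tan δ. A base at or above the horizon (δ ≤ 0) has no
distance; such detections are dropped and counted. The flat-ground model is
the main physical assumption of this stage; terrain slope translates
directly into ranging error, which is why the verification stage exists.

### Stage 2A: three-image consistency

For each candidate, the `k_images` = 3 nearest stations (planar distance,
ties by station id) are queried through a detector contract
`(station, candidate) -> observation | None`. The candidate survives iff
every queried image yields an observation and all pairwise distances among
the observed positions are **strictly below** `consistency_distance` = 4 m;
it is then repositioned at the arithmetic centroid. The detector contract
lets any detector back this check; the synthetic scene provides one backed
by its own simulated detections ("nearest observation of that station
within 4 m of the candidate").

### Stage 2B: spectral filtering

Each candidate's 50 cm buffer over the seven-band ortho stack (R14, G14,
B14, R17, G17, B17, NIR17; fixed feature order, mean then sd per band)
yields 14 zonal features. Standard deviation uses the **population (n)
divisor** — with ~13 pixels per buffer the n vs n−1 choice shifts sd by
4%, so it is fixed and stated. Buffer membership is center-in-circle,
consistent with clipping. Candidates whose buffer misses the rasters are
dropped and counted (no spectral evidence either way).

Feature selection is a single-step permutation-importance ranking from a
seeded random forest (`keep_fraction` or `importance_threshold`; the top
feature is always retained). The classifier default is a 200-tree random
forest; a 16-unit single-hidden-layer network and linear/radial SVMs
(posterior-calibrated) sit behind the same interface. Accuracy is reported
from repeated stratified k-fold cross-validation: 3 replicates (the
replicate count is the procedure's defining parameter) × 10 folds by
default, both configurable. Candidates are kept when the TREE posterior is
≥ `decision_threshold` (0.5).

### Merging

Candidates closer than `merge_distance` = 4 m are artifacts of one tree.
Buffers of radius 2 m intersect exactly when centers are < 4 m apart
(tangency at exactly 4 m does **not** merge); connected components collapse
to their member centroid (point centroid by default; the union-polygon
centroid is available and coincides for pairs), height = max member height,
id deterministic from sorted member ids. Chained components can leave new
centroids < 4 m apart, so merging iterates to a fixed point (bounded by n
passes); `single_pass` preserves strict one-shot behavior. A ring of
candidates around an isolated point is the canonical case where the two
differ (see tests).

### Evaluation

Matching uses candidate-side criteria at `match_distance` = 5 m (strict
inequality): a candidate is TP iff its nearest truth point is within range
and no other candidate is closer to that truth point (distance ties by
candidate id); otherwise FP. A truth point is FN iff no candidate is within
range. This is deliberately **not** a global assignment: a truth point can
be neither matched nor FN, so TP+FN may undercount the reference — the
only reading consistent with published inventories of this design, where
TP+FN is smaller than the zone tree count. Metrics are percentages rounded
half-away-from-zero to 2 decimals; F1 is computed from *unrounded* p and r
(rounding first corrupts the second decimal). TP = 0 gives p = r = F1 = 0
by convention. Pooled metrics sum TP/FP/FN across zones first.

## The scene simulator

`scene_sim` emulates the input suite end-to-end with exact truth:

* **Layout.** Street trees at arc-length multiples of
  `street_tree_spacing` (default 10 m) along each axis, both endpoints
  included, offset 3 m to the left of travel (a sidewalk row; also keeps
  trees outside the 2.5 m flat-ground blind radius of the nearest camera).
  Park trees are Poisson-placed at `park_tree_density` per hectare and
  thinned to `min_tree_spacing` (4 m). No tree center inside a building.
  Heights uniform in 6–15 m, crown radii in 1.5–3 m.
* **Point cloud.** Uniform first returns at 14 /m²; surface = max of
  paraboloid crowns z(r) = h(1 − (r/R)²), flat roofs (8 m), pole cylinders,
  ground 0; Gaussian noise (sd 0.1 m, clipped ±0.5 m) on non-ground
  returns only. Realized density is exact up to rounding.
* **Ortho.** 0.25 m pixels; crown-disc pixels draw from the TREE spectral
  class, everything else from NOT-TREE. Default class means are ≥ 10 sd
  apart on NIR, so spectral separability is controlled and near-perfect by
  construction.
* **Detections.** Each station sees every unoccluded tree within 40 m;
  pixels are the *exact inverse* of the geolocation model applied to true
  bearing/distance plus configurable noise, so zero-noise relocation is
  exact to float precision. Spurious detections (Poisson per image) and
  misses are injected at configurable rates. Occlusion is
  building-segment intersection only; trees do not occlude each other.
* **Clutter.** Optional "poles": tall thin objects rendered into the cloud
  (hence ALS stage-1 false positives) but spectrally NOT-TREE and invisible
  to the image detector, so both stage-2 variants can remove them.
* **Determinism.** Every artifact draws from its own child stream of the
  scene seed; identical configs give bitwise-identical scenes.

The benchmark district (`demo_city_config`) is 200 m × 200 m with four
streets (7.5 m tree spacing, ~112 trees), two building blocks, six poles
and two expected spurious detections per image, at zero detection noise.
Problem sizes throughout (40×40 oracle rasters, 2 000 training points
against the real study's 15 766, the 200 m benchmark) are chosen so the
full suite runs in a couple of minutes on one CPU while every code path is
exercised at realistic densities.

**What passing tests show — and don't.** The simulator shares its
projection model with the geolocator (by design: it makes the contract
exactly invertible), draws spectra from clean per-class Gaussians, and
assumes flat ground. Passing therefore demonstrates internal correctness
of every stage and of their composition, not real-world accuracy: real
panoramas violate flat ground, real spectra overlap across classes and
seasons, real clouds have occlusion and registration error. On the
benchmark, the four street-end trees whose third-nearest panorama is
beyond the 40 m range are rejected by the 3-image check — a faithful
reproduction of that check's behavior at route ends, and the reason its
true-positive retention is ~96% rather than 100%.

## Known limitations

* No CRS/reprojection support; inputs must share one planar frame.
* LAS/LAZ is not read; point clouds are XYZ text (rasters are TIFF + TFW).
* No CNN detector is included; stage 1A consumes detections through the
  provider contract (CSV schema or the synthetic detector).
* Crown segmentation, species/health attributes and crown metrics are out
  of scope.
* The image-consistency check requires ≥ 3 stations within detection range;
  sparse routes (cul-de-sacs, route ends) lose true positives there.
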