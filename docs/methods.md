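# Methods

## Problem setting

A z-stack of a tightly packed multilayer tissue is segmented per slice
(e.g. by watershed) and the slices of each cell are linked by a tracking
step. After those stages each cell *i* is a sparse set of 3D boundary
points *X<sub>i</sub>* — the pixel centers of its wall in the 2–4 planes
that cut it. The task is to assign every point of a dense interior cloud
*P* to a cell, producing full 3D shapes and volumes. This package starts
where segmentation and tracking end; it neither segments nor tracks.

## Tessellation models

**Euclidean Voronoi.** Site of cell *i* = arithmetic mean of
*X<sub>i</sub>* (a proxy for the nucleus position when nuclei are not
imaged). A cloud point joins its nearest site. Bisectors are planes and
regions convex, so the model cannot express neighboring cells of very
different sizes or orientations.

**Adaptive quadratic Voronoi (AQVT).** Cell *i* is parameterized by the
pair (*c<sub>i</sub>*, *M<sub>i</sub>*) of its boundary points' minimum
volume enclosing ellipsoid; a cloud point *x* joins the cell minimizing
(*x* − *c<sub>i</sub>*)ᵀ*M<sub>i</sub>*(*x* − *c<sub>i</sub>*). The
rationale: wall points of adjacent cells lie on or near both cells'
enclosing ellipsoids, so the Mahalanobis bisector passes close to the
sampled walls, and the per-cell metric encodes each cell's own elongation.
No additive weights are used (the general anisotropic diagram's weight
term is fixed to zero), and the diagram is invariant under a global
rescaling of all metrics — equivalently, it is the fixed point of
uniformly inflating all ellipsoids until they tile.

Assignment is by explicit distance evaluation of every point against every
site (a few hundred sites at most; ~10⁶–10⁷ points), which is exact,
deterministic and fast enough that no spatial index is warranted. Ties at
bisectors go to the smaller cell id so that labeling is a total partition;
bisectors have measure zero, so this choice is cosmetic.

## MVEE solver

The Löwner–John problem is solved through its dual: maximize
log det Σ *u<sub>q</sub>* *q* *q*ᵀ over barycentric weights *u* on the
lifted points *q* = (*p*, 1). The iteration is Khachiyan's coordinate
ascent augmented with Wolfe–Atwood "away" steps: each step either raises
the weight of the point with the largest leverage κ or lowers (possibly to
zero) the weight of the support point with the smallest κ. Away steps with
κ ≤ 1 drop the point outright; the closed-form step length applies only
for κ > 1. Plain first-order ascent needs on the order of 1/tol
iterations; with away steps a few hundred suffice at tol = 1e-4 on
realistic per-cell point sets (hundreds to thousands of points), well
under the 10,000-iteration cap.

Convergence is declared when the dual gap ε = max κ/(d+1) − 1 falls below
tol·d/(d+1), which guarantees every point satisfies
(*p* − *c*)ᵀ*M*(*p* − *c*) ≤ 1 + tol with *M* = cov⁻¹/d. Because the
weighted mean of κ is exactly d+1, some point always has Mahalanobis value
≥ 1, certifying minimality: the (1+tol)-shrunken ellipsoid excludes it.
Rank-deficient inputs (e.g. all points coplanar in 3D) have no
finite-volume minimizer and are rejected at this layer with the count of
deficient dimensions; the tessellation layer handles them instead by
symmetric extrusion: each cell seen in a single plane has its points
duplicated at ±`plane_epsilon` (default 0.3 µm, about one slice
half-spacing at the densest resampling) along each deficient axis before
fitting, and the cell is flagged. The resulting smallest semi-axis is
between `plane_epsilon` and √3·`plane_epsilon`.

## Tissue surface and dense cloud

The tissue is modeled as a height field z = f(x, y) over a flat base plane
at the lowest contour z — the dome-over-base geometry of an apical
meristem. Per-slice outer contours of the foreground (pixels touching
background or the image border, 4-connectivity) provide scattered samples;
f is fitted on an n×n grid (default 64×64) by linear least squares with
bilinear interpolation at the samples plus a smoothness term (default
λ = 1e-3, dimensionless on index-normalized coordinates) that penalizes
mismatches of first differences at neighboring nodes — along each axis and
across axes. The penalty's null space is exactly the planes, so any plane
is reproduced to machine precision and the system is nonsingular whenever
three non-collinear samples exist and λ > 0. The dense cloud is the
regular lattice of points between the base plane and the surface. For
box-shaped phantoms the surface step is bypassed and the cloud is simply
every voxel center, which keeps estimated volumes commensurate with
voxel-counting ground truth.

An evolving active contour adds nothing when inputs already carry labels,
so contour extraction is a direct boundary operation by design, not an
emulation of a level-set method.

## Synthetic phantoms

`generate_quadratic_tissue` draws sites uniformly in a box with a minimum
pairwise separation (default 3 µm, rejection sampling) and gives each cell
a random metric *R*ᵀdiag(λ)*R* with a uniform random rotation and
eigenvalues uniform in [rmin², rmax²] (default axis ratios up to 3),
normalized to unit determinant so the metric sets shape, not size; every
voxel center is then labeled by quadratic-nearest site. Defaults: 50 cells
in a 15 × 15 × 16.2 µm box at 0.2 × 0.2 × 0.225 µm voxels, giving a mean
equivalent diameter of ~5.2 µm — the scale of meristematic cells. The 2D
generator is analogous with axis-aligned metrics diag(e, 1/e), elongation
e uniform in [2, 4] along the longitudinal (y) axis, and site separation
tested in mean-elongation-stretched coordinates so elongated cells keep
proportionally larger longitudinal spacing.

`slice_phantom` keeps z-planes every `z_spacing` µm (a seeded random
offset within one spacing, snapped to voxel planes) and emits, per cell
and plane, the pixel centers adjacent to a different label or to the image
border — watershed-style wall points already clustered by cell, which is
exactly the input contract of the reconstruction. An optional Gaussian
in-plane jitter (σ in µm) emulates segmentation noise. `slice_lines` is
the 2D analogue with lines of constant y. All randomness flows through
`numpy.random.default_rng(seed)` with a fixed draw order (sites, then
per-cell rotations and eigenvalues), so phantoms are bit-reproducible
across platforms.

What the phantom does *not* emulate: intensity formation (PSF, noise,
bleaching), segmentation/tracking failures, temporal growth, and — 
importantly — the shape statistics of real cells (next section).

## Validation machinery

- **Modified Hausdorff Distance** (Dubuisson–Jain): the larger of the two
  directed mean nearest-neighbor distances between point sets; symmetric,
  nonnegative, zero exactly when the sets are equal. Nearest neighbors via
  a k-d tree; tests cross-check against a brute-force double loop.
- **Reslicing**: the reconstructed cloud points within a slab
  |z − z₀| ≤ slab_tol (default half the lattice dz, selecting one lattice
  layer) are reduced per cell to their boundary ring and compared with the
  segmented cross-section at that depth.
- **Volume error**: per-cell |est − truth|/truth in percent; reports give
  the mean and sample standard deviation (ddof = 1) across cells. Default
  volume estimator is assigned-point count × lattice cell volume,
  like-for-like with voxel-counting ground truth; convex-hull volumes are
  used for meshes.
- **Sparsity sweep**: slice → fit → assign → score at a ladder of
  z-spacings, for either method.

## Accuracy on this phantom class — an honest account

When the reconstruction is given the *true* (c, M) pairs it reproduces
the phantom exactly (the assignment is the generator run backwards). With
MVEE-estimated parameters, mislabeled voxels are confined to roughly
one-voxel-thick shells at the walls (90th-percentile distance to the
nearest true wall ≈ 0.3 µm), yet per-cell volume errors average ~8–12% at
3–5 slices/cell and ~7–10% even at near-dense slicing, with a long tail
from the smallest cells.

The reason is structural: the MVEE of a Voronoi-type polyhedral region is
not proportional to the metric that generated it, and its inflation factor
varies with the region's local shape, so the fitted metrics displace each
bisector by a sub-voxel to one-voxel amount that does not cancel between
neighbors of different sizes. At a 5 µm cell size one voxel of wall is
~20% of the volume, so percent-volume statistics amplify what is an
excellent *shape* reconstruction. Uniform-site phantoms have a cell-volume
coefficient of variation ≈ 0.33; real meristem tissue is far more
size-uniform and its compact, ellipsoid-like cells are much closer to a
configuration where every wall point lies on both neighbors' enclosing
ellipsoids — the regime in which quadratic bisectors reproduce walls
exactly. Reported volume errors on real tissue of that kind (≈3% dense,
≈5% at 3 slices/cell) are therefore *smaller* than on this phantom class,
and the phantom numbers here should be read as a stress test, not an upper
bound on real-data accuracy. The comparative conclusions are robust in
both regimes: the quadratic tessellation beats the Euclidean baseline at
every sparsity level (here ≈9–12% vs ≈19–20% mean volume error), error
degrades only weakly as slicing coarsens, and 2D shape recovery on
elongated cells reaches a mean MHD of ~2.5–3% of the mean longitudinal
diameter at 3 lines/cell.

Problem sizes used in the shipped experiments: 50-cell 3D phantoms
(75 × 75 × 72 voxels) and 200-cell 2D phantoms (1250 × 300 pixels), chosen
to match the cell scale and voxel size above while keeping a full
reconstruct-and-score cycle in the tens of seconds.

## Numerical choices and edge cases

- All geometry is in physical µm; voxel index (i, j, k) maps to center
  ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz), 0-based, half-open extents;
  conversion happens once at the I/O boundary.
- MVEE: tol 1e-4, cap 10,000 iterations; the solver reports the achieved
  containment tolerance and the dual weights (support points).
- Assignment ties → smallest cell id; duplicate Euclidean sites are
  rejected as ambiguous.
- Cells with fewer than 4 assigned non-coplanar points have no hull; they
  are reported in a failure map, never silently dropped.
- Cells intersecting no sampled plane are listed as missed and excluded
  from error statistics (reported separately).
- A cell's MVEE can be inflated by a tracking outlier; rather than guess a
  rejection rule the site set exposes per-cell diagnostics (semi-axes,
  volumes) for the caller to screen.

## Known limitations

- Accuracy depends on walls being observed: unsampled cell caps (the
  z-extremes between two imaging planes) are split by extrapolated
  bisectors.
- The tessellation fills its domain; background/void inside the tissue
  mask is not modeled.
- Exact combinatorial bisector geometry (quadric arrangements) is out of
  scope; all regions are represented by labeled point clouds and their
  convex hulls.
- The 2D experiment assumes axis-aligned elongation; arbitrary 2D
  rotations are supported by the solver but not exercised by the
  generator.
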