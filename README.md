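# aqvt — 3D cell-shape reconstruction from sparse confocal slices

Live imaging of a growing, tightly packed tissue — the shoot apical meristem
of *Arabidopsis* is the motivating case — forces a hard trade-off: to keep
cells alive under the laser, a confocal z-stack can only afford 2–4 optical
sections per cell. Classical 3D segmentation cannot recover cell shapes and
volumes from so few slices. This package reconstructs full 3D cells from
such sparse, pre-segmented and pre-tracked cross-sections by exploiting the
one thing a packed tissue guarantees: the cells tessellate space.

## Method

Each tracked cell *i* contributes a sparse set of boundary points
*X<sub>i</sub>* pooled over its slices. Two tessellations of a dense
interior point cloud *P* are provided:

- **Euclidean Voronoi baseline.** The site of cell *i* is the centroid of
  *X<sub>i</sub>*; each point of *P* joins its nearest site. Adequate when
  cells are isotropic and uniformly sized, poor otherwise.
- **Adaptive quadratic Voronoi tessellation (AQVT).** The minimum-volume
  enclosing ellipsoid (MVEE, the Löwner–John ellipsoid) of *X<sub>i</sub>*
  is fitted by Khachiyan's dual ascent, giving a center *c<sub>i</sub>* and
  a symmetric positive-definite shape matrix *M<sub>i</sub>*. Point *x*
  joins the cell minimizing the squared Mahalanobis distance
  (*x* − *c<sub>i</sub>*)ᵀ *M<sub>i</sub>* (*x* − *c<sub>i</sub>*).
  Because every cell carries its own metric, estimated from its own sparse
  data, the diagram adapts to anisotropic shapes and sizes; bisectors are
  quadratic surfaces. Scaling all metrics by a common positive factor
  leaves the tessellation unchanged.

Around this core the package provides: tissue-surface fitting (a
regularized bilinear height field over per-slice contours) and dense
interior-cloud sampling; a synthetic phantom generator that produces
ground-truth quadratic-Voronoi tissues and emulates segmented + tracked
sparse slicing; and validation tools — computational reslicing, the
Modified Hausdorff Distance (MHD), per-cell volume-error reports, and
volume-error-versus-sparsity sweeps.

## Worked example

Reconstruct a 20-cell phantom from ~4 slices per cell:

```python
import numpy as np
from aqvt import (generate_quadratic_tissue, slice_phantom,
                  reconstruct_from_stack, volume_error_report, label_agreement)

vol = generate_quadratic_tissue(n_cells=20, domain=(11.0, 11.0, 11.25), seed=7)
stack = slice_phantom(vol, z_spacing=1.35, seed=7)
print(f"cells: {len(stack.cells)}, planes: {len(stack.z_planes)}, "
      f"mean slices/cell: {np.mean([c.n_slices for c in stack.cells]):.1f}")

tess = reconstruct_from_stack(vol, stack, method="aqvt")
report = volume_error_report(tess.per_cell_volume, vol.truth_volumes)
agree = label_agreement(tess.labels.reshape(vol.labels.shape), vol)
print(f"mean |volume error|: {report.mean:.2f}% of truth "
      f"(std {report.std:.2f}%), voxel label agreement: {agree:.3f}")
print(f"cell 1: estimated {tess.per_cell_volume[1]:.1f} um^3, "
      f"truth {vol.truth_volumes[1]:.1f} um^3")
```

prints

```
cells: 20, planes: 8, mean slices/cell: 4.2
mean |volume error|: 8.55% of truth (std 7.40%), voxel label agreement: 0.882
cell 1: estimated 98.0 um^3, truth 91.8 um^3
```

The phantom is a ground-truth quadratic-Voronoi tissue at confocal voxel
size (0.2 × 0.2 × 0.225 µm); `slice_phantom` keeps only every sixth
z-plane and emits per-cell wall points, mimicking watershed segmentation
plus tracking at live-imaging sparsity. The reconstruction recovers each
cell's volume to within a few percent on average and labels ~88% of all
voxels identically to the ground truth; the remaining disagreements sit in
roughly one-voxel-thick shells along the cell walls.

The same pipeline is available from the shell:

```sh
aqvt phantom --n-cells 50 --seed 1 --out truth.tif
aqvt slice --stack truth.tif --z-spacing 1.35 --seed 1 --out points.csv
aqvt reconstruct --points points.csv --stack truth.tif --meshes --out recon/
aqvt validate --pred recon/reconstruction.tif --truth truth.tif --out errors.csv
aqvt sweep --stack truth.tif --spacings 0.45,0.675,0.9,1.125,1.35 --out sweep.csv
```

`reconstruct --meshes` exports each cell as an ASCII PLY convex polyhedron
with a manifest of vertex counts and hull volumes.

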