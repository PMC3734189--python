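"""Global tissue surface and the dense interior point cloud.

The tissue (e.g. a shoot-apex dome) is modeled as a height field
``z = f(x, y)`` over a flat base plane.  Per-slice outer contours of the
imaged tissue provide scattered samples of f; a regularized bilinear
least-squares fit interpolates them onto a rectangular grid, and a regular
lattice of points between the base plane and the surface forms the dense
cloud P that the tessellation partitions into cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator
from skimage.segmentation import find_boundaries

from .errors import ConditioningError, ValidationError

__all__ = [
    "HeightSurface",
    "DenseCloud",
    "extract_tissue_contours",
    "fit_height_surface",
    "sample_interior_cloud",
]

logger = logging.getLogger(__name__)


@dataclass
class HeightSurface:
    """Gridded surface ``z = f(x, y)`` above a flat base plane at ``base_z``."""

    grid_x: np.ndarray  # (nx,) strictly increasing, µm
    grid_y: np.ndarray  # (ny,) strictly increasing, µm
    heights: np.ndarray  # (nx, ny), µm
    base_z: float

    def __post_init__(self):
        if np.any(np.diff(self.grid_x) <= 0) or np.any(np.diff(self.grid_y) <= 0):
            raise ValidationError("grid coordinates must be strictly increasing")
        if self.heights.shape != (self.grid_x.size, self.grid_y.size):
            raise ValidationError("heights must have shape (nx, ny)")
        if not np.all(np.isfinite(self.heights)):
            raise ValidationError("heights must be finite")

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.grid_x, self.grid_y),
            self.heights,
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )

    def __call__(self, xy) -> np.ndarray:
        return self.interpolator()(np.atleast_2d(np.asarray(xy, dtype=float)))


@dataclass
class DenseCloud:
    """Regular lattice of interior points (µm) with its spacing."""

    points: np.ndarray  # (N, 3)
    spacing: tuple[float, float, float]

    @property
    def point_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


def extract_tissue_contours(stack, voxel_size) -> list[np.ndarray]:
    """Outer boundary of the tissue foreground, slice by slice.

    ``stack`` is a (nz, ny, nx) label or binary array; any nonzero voxel is
    foreground.  For each slice the foreground pixels that touch background
    or the image border (4-connectivity) are returned as ordered (x, y, z)
    pixel centers in µm; the ordering walks the contour by polar angle
    around the slice centroid, which is adequate for the star-convex
    cross-sections of dome-shaped tissues.
    """
    labels = np.asarray(stack)
    if labels.ndim != 3 or labels.size == 0:
        raise ValidationError("stack must be a non-empty (nz, ny, nx) array")
    dx, dy, dz = voxel_size
    contours = []
    any_fg = False
    for k in range(labels.shape[0]):
        fg = labels[k] > 0
        if not fg.any():
            logger.warning("slice %d: empty foreground, skipped", k)
            contours.append(np.empty((0, 3)))
            continue
        any_fg = True
        padded = np.pad(fg, 1, constant_values=False)
        ring = find_boundaries(padded, mode="inner", connectivity=1)[1:-1, 1:-1]
        ring &= fg
        iy, ix = np.nonzero(ring)
        x = (ix + 0.5) * dx
        y = (iy + 0.5) * dy
        ang = np.arctan2(y - y.mean(), x - x.mean())
        order = np.lexsort((np.hypot(x - x.mean(), y - y.mean()), ang))
        z = np.full(x.size, (k + 0.5) * dz)
        contours.append(np.column_stack([x[order], y[order], z]))
    if not any_fg:
        raise ValidationError("all slices have empty foreground")
    return contours


def _bilinear_design(x, y, grid_x, grid_y) -> sp.csr_matrix:
    nx, ny = grid_x.size, grid_y.size
    ix = np.clip(np.searchsorted(grid_x, x, side="right") - 1, 0, nx - 2)
    iy = np.clip(np.searchsorted(grid_y, y, side="right") - 1, 0, ny - 2)
    tx = (x - grid_x[ix]) / (grid_x[ix + 1] - grid_x[ix])
    ty = (y - grid_y[iy]) / (grid_y[iy + 1] - grid_y[iy])
    rows, cols, vals = [], [], []
    m = x.size
    idx = np.arange(m)
    for di, wx in ((0, 1 - tx), (1, tx)):
        for dj, wy in ((0, 1 - ty), (1, ty)):
            rows.append(idx)
            cols.append((ix + di) * ny + (iy + dj))
            vals.append(wx * wy)
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, nx * ny),
    )


def _gradient_mismatch_penalty(nx: int, ny: int) -> sp.csr_matrix:
    """Rows penalizing differences of adjacent first differences.

    The first difference of the height field at a node is compared with the
    first difference at the neighboring node, along the same axis (a second
    difference) and across the other axis (a mixed difference).  Planes
    (constant gradient) incur zero penalty, and the null space of the
    penalty is exactly the space of planes, so the regularized system is
    nonsingular once three non-collinear samples pin the plane down.
    """

    def second_diff(n):
        return sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(max(n - 2, 0), n))

    def first_diff(n):
        return sp.diags([-1.0, 1.0], [0, 1], shape=(max(n - 1, 0), n))

    ix, iy = sp.identity(nx), sp.identity(ny)
    blocks = [
        sp.kron(second_diff(nx), iy),  # along-x gradient mismatch
        sp.kron(ix, second_diff(ny)),  # along-y gradient mismatch
        sp.kron(first_diff(nx), first_diff(ny)),  # cross-axis mismatch
    ]
    return sp.vstack(blocks).tocsr()


def fit_height_surface(
    contour_points,
    grid: tuple[int, int] = (64, 64),
    smoothness: float = 1e-3,
) -> HeightSurface:
    """Least-squares bilinear height field through scattered contour points.

    Minimizes the sum of squared bilinear-interpolation residuals at the
    samples plus ``smoothness`` times the squared mismatch of first
    differences at neighboring grid nodes (in index-normalized coordinates).
    Any exactly-representable plane is reproduced to machine precision.
    """
    pts = np.asarray(contour_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("contour_points must be (n, 3)")
    if smoothness < 0:
        raise ValidationError("smoothness must be nonnegative")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    xy = np.column_stack([x, y])
    if pts.shape[0] < 3 or np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ConditioningError(
            "need at least 3 non-collinear (x, y) samples to fit a surface"
        )
    nx, ny = grid
    grid_x = np.linspace(x.min(), x.max(), nx)
    grid_y = np.linspace(y.min(), y.max(), ny)
    A = _bilinear_design(x, y, grid_x, grid_y)
    D = _gradient_mismatch_penalty(nx, ny)
    lhs = (A.T @ A + smoothness * (D.T @ D)).tocsc()
    rhs = A.T @ z
    try:
        lu = spla.splu(lhs)
        h = lu.solve(rhs)
    except RuntimeError as exc:
        raise ConditioningError(
            f"surface system is singular ({exc}); try smoothness > 0"
        ) from None
    if not np.all(np.isfinite(h)):
        raise ConditioningError("surface solve produced non-finite heights; "
                                "try smoothness > 0")
    heights = h.reshape(nx, ny)
    return HeightSurface(
        grid_x=grid_x, grid_y=grid_y, heights=heights, base_z=float(z.min())
    )


def sample_interior_cloud(
    surf: HeightSurface, spacing: tuple[float, float, float]
) -> DenseCloud:
    """Regular lattice of points with ``base_z <= z <= f(x, y)``."""
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValidationError("spacing must be positive")
    x0, x1 = surf.grid_x[0], surf.grid_x[-1]
    y0, y1 = surf.grid_y[0], surf.grid_y[-1]
    z1 = float(surf.heights.max())
    if dx > (x1 - x0) or dy > (y1 - y0):
        raise ValidationError("spacing exceeds the surface domain extent")
    eps = 1e-9
    xs = np.arange(x0, x1 + eps * max(1.0, abs(x1)), dx)
    ys = np.arange(y0, y1 + eps * max(1.0, abs(y1)), dy)
    zs = np.arange(surf.base_z, z1 + eps * max(1.0, abs(z1)), dz)
    if zs.size == 0:
        zs = np.array([surf.base_z])
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    f = surf.interpolator()(np.column_stack([X.ravel(), Y.ravel()]))
    f = f.reshape(X.shape)
    pts = []
    for z in zs:
        keep = z <= f + 1e-9
        pts.append(np.column_stack([X[keep], Y[keep], np.full(int(keep.sum()), z)]))
    points = np.vstack(pts) if pts else np.empty((0, 3))
    return DenseCloud(points=points, spacing=(dx, dy, dz))
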