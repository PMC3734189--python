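"""Synthetic tissue phantoms with known ground truth.

The generator produces tightly packed label volumes in the quadratic-Voronoi
model class: sites with per-cell anisotropic metrics partition every voxel,
so there are no gaps or voids, exactly like a meristem-style tissue.  A
slicing operation then emulates the output of per-slice segmentation plus
cell tracking — sparse, pre-clustered cell-wall points on a handful of
imaging planes — which is the input the reconstruction consumes.

Because the ground truth is generated in the same model class the method
assumes, pipeline tests measure parameter/shape recovery against a known
answer; an optional Gaussian boundary jitter emulates segmentation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PackingError, ValidationError
from .mvee import Ellipsoid
from .tessellation import CellSliceSet, QuadraticSiteSet, assign_quadratic

__all__ = [
    "LabelVolume",
    "SparseStack",
    "generate_quadratic_tissue",
    "slice_phantom",
    "generate_2d_elongated_tissue",
    "slice_lines",
    "voxel_centers",
    "mean_axis_extent",
]

# Voxel size matching a typical high-resolution confocal superpixel (µm).
DEFAULT_VOXEL_SIZE = (0.2, 0.2, 0.225)
# Minimum pairwise site separation (µm), to avoid sliver cells.
DEFAULT_MIN_SEPARATION = 3.0


@dataclass
class LabelVolume:
    """Voxelized tissue with one integer cell id per voxel (0 = background).

    ``labels`` is ``(nz, ny, nx)`` for 3-D tissues or ``(ny, nx)`` for 2-D
    ones; ``voxel_size`` is ``(dx, dy, dz)`` or ``(dx, dy)`` in µm.  Voxel
    index ``(i, j, k)`` maps to the physical center
    ``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``.
    """

    labels: np.ndarray
    voxel_size: tuple
    truth_sites: QuadraticSiteSet | None = None
    truth_volumes: dict[int, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if self.labels.ndim != len(self.voxel_size):
            raise ValidationError(
                f"labels are {self.labels.ndim}-D but voxel_size has "
                f"{len(self.voxel_size)} entries"
            )

    @property
    def dim(self) -> int:
        return self.labels.ndim

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SparseStack:
    """Sparse per-cell wall samples on a subset of imaging planes."""

    cells: list[CellSliceSet]
    z_planes: list[float]
    z_spacing: float
    missed_cells: list[int] = field(default_factory=list)


def voxel_centers(vol: LabelVolume) -> np.ndarray:
    """Physical centers of all voxels, ``(N, d)`` in (x, y[, z]) order.

    The row order matches ``vol.labels.ravel()``.
    """
    if vol.dim == 3:
        dx, dy, dz = vol.voxel_size
        nz, ny, nx = vol.labels.shape
        zs = (np.arange(nz) + 0.5) * dz
        ys = (np.arange(ny) + 0.5) * dy
        xs = (np.arange(nx) + 0.5) * dx
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dx, dy = vol.voxel_size
    ny, nx = vol.labels.shape
    ys = (np.arange(ny) + 0.5) * dy
    xs = (np.arange(nx) + 0.5) * dx
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel()])


def mean_axis_extent(vol: LabelVolume, axis: str) -> float:
    """Mean per-cell bounding extent (µm) along ``axis`` in {'x','y','z'}."""
    order = {"x": -1, "y": -2, "z": -3}[axis]
    step = vol.voxel_size[{"x": 0, "y": 1, "z": 2}[axis]]
    extents = []
    for sl in ndimage.find_objects(vol.labels):
        if sl is None:
            continue
        s = sl[order]
        extents.append((s.stop - s.start) * step)
    if not extents:
        raise ValidationError("volume contains no labeled cells")
    return float(np.mean(extents))


def _random_rotation(rng: np.random.Generator, d: int) -> np.ndarray:
    A = rng.normal(size=(d, d))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _sample_sites(rng, n_cells, domain, min_separation, metric_scale=None):
    """Uniform sites with a minimum pairwise separation (rejection sampling).

    ``metric_scale`` optionally divides each coordinate before the
    separation test, so elongated tissues keep proportionally larger
    spacing along their long axis.
    """
    d = len(domain)
    scale = np.ones(d) if metric_scale is None else np.asarray(metric_scale)
    sites = []
    max_attempts = 2000 * n_cells
    for _ in range(max_attempts):
        cand = rng.uniform(0.0, 1.0, d) * np.asarray(domain)
        ok = True
        for s in sites:
            if np.linalg.norm((cand - s) / scale) < min_separation:
                ok = False
                break
        if ok:
            sites.append(cand)
            if len(sites) == n_cells:
                return np.array(sites)
    raise PackingError(
        f"placed only {len(sites)}/{n_cells} sites with separation "
        f"{min_separation} in domain {domain}"
    )


def generate_quadratic_tissue(
    n_cells: int = 50,
    domain: tuple[float, float, float] = (15.0, 15.0, 16.2),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    anisotropy_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> LabelVolume:
    """Seeded 3-D ground-truth tissue in the quadratic-Voronoi model class.

    Sites are drawn uniformly in ``domain`` (µm) with a minimum pairwise
    separation; each cell's metric is ``R^T diag(lams) R`` with a uniformly
    random rotation and eigenvalues uniform in
    ``[anisotropy_range[0]^2, anisotropy_range[1]^2]`` (axis ratios up to
    ``rmax/rmin``).  Every voxel center is labeled by quadratic-nearest
    site, so the tissue is gap- and overlap-free.  The default domain packs
    about fifty cells of 5–6 µm diameter.
    """
    rmin, rmax = anisotropy_range
    if n_cells < 2:
        raise ValidationError("need at least 2 cells")
    if not (rmax >= rmin >= 1.0):
        raise ValidationError("anisotropy_range must satisfy rmax >= rmin >= 1")
    rng = np.random.default_rng(seed)
    sites = _sample_sites(rng, n_cells, domain, min_separation)
    entries = []
    for k in range(n_cells):
        R = _random_rotation(rng, 3)
        lams = rng.uniform(rmin**2, rmax**2, size=3)
        # Eigenvalues encode axis ratios only: normalize to unit determinant
        # so cell size is set by the packing, not by the metric draw.
        lams /= lams.prod() ** (1.0 / 3.0)
        M = R.T @ np.diag(lams) @ R
        entries.append((k + 1, Ellipsoid(center=sites[k], shape=M)))
    site_set = QuadraticSiteSet(entries=entries)

    dx, dy, dz = voxel_size
    shape = (
        int(round(domain[2] / dz)),
        int(round(domain[1] / dy)),
        int(round(domain[0] / dx)),
    )
    vol = LabelVolume(
        labels=np.zeros(shape, dtype=np.int32),
        voxel_size=voxel_size,
        truth_sites=site_set,
        seed=seed,
    )
    t = assign_quadratic(voxel_centers(vol), site_set)
    vol.labels = t.labels.reshape(shape).astype(np.int32)
    counts = np.bincount(vol.labels.ravel(), minlength=n_cells + 1)
    vol.truth_volumes = {
        cid: float(counts[cid]) * vol.voxel_volume for cid in range(1, n_cells + 1)
    }
    return vol


def _wall_mask(slice_labels: np.ndarray) -> np.ndarray:
    """Pixels 4-adjacent to a different label or to the image border."""
    padded = np.pad(slice_labels, 1, constant_values=-1)
    core = padded[1:-1, 1:-1]
    mask = np.zeros(core.shape, dtype=bool)
    mask |= padded[:-2, 1:-1] != core
    mask |= padded[2:, 1:-1] != core
    mask |= padded[1:-1, :-2] != core
    mask |= padded[1:-1, 2:] != core
    return mask


def _snap_planes(rng, extent, spacing, step):
    """Plane coordinates ``offset + m*spacing`` snapped to voxel planes."""
    n_planes = int(np.floor(extent / step))
    offset = rng.uniform(0.0, spacing)
    planes = np.arange(offset, extent, spacing)
    idx = np.clip(np.round(planes / step - 0.5).astype(int), 0, n_planes - 1)
    return sorted(set(idx.tolist()))


def slice_phantom(
    vol: LabelVolume,
    z_spacing: float,
    seed: int = 0,
    jitter_sigma: float = 0.0,
) -> SparseStack:
    """Resample a dense label volume at sparse z-planes, emitting wall points.

    Planes are taken every ``z_spacing`` µm (random in-spacing offset drawn
    from ``seed``), snapped to voxel planes.  Within each selected plane,
    every cell contributes the pixel centers that touch a different label
    or the image border (4-connectivity) — the analogue of watershed wall
    points already clustered per cell by tracking.  ``jitter_sigma`` adds
    Gaussian in-plane noise (µm) to emulate segmentation error.  Cells
    intersecting no selected plane are listed in ``missed_cells``.
    """
    if vol.dim != 3:
        raise ValidationError("slice_phantom needs a 3-D volume")
    dx, dy, dz = vol.voxel_size
    if z_spacing < dz:
        raise ValidationError(f"z_spacing {z_spacing} < voxel dz {dz}")
    rng = np.random.default_rng(seed)
    nz = vol.labels.shape[0]
    plane_idx = _snap_planes(rng, nz * dz, z_spacing, dz)

    per_cell: dict[int, list[np.ndarray]] = {}
    z_planes = []
    for k in plane_idx:
        sl = vol.labels[k]
        z = (k + 0.5) * dz
        z_planes.append(z)
        wall = _wall_mask(sl)
        iy, ix = np.nonzero(wall)
        labs = sl[iy, ix]
        x = (ix + 0.5) * dx
        y = (iy + 0.5) * dy
        if jitter_sigma > 0:
            x = x + rng.normal(0.0, jitter_sigma, x.size)
            y = y + rng.normal(0.0, jitter_sigma, y.size)
        for cid in np.unique(labs):
            if cid == 0:
                continue
            m = labs == cid
            pts = np.column_stack([x[m], y[m], np.full(int(m.sum()), z)])
            per_cell.setdefault(int(cid), []).append(pts)

    cells = [
        CellSliceSet(cell_id=cid, points=np.vstack(chunks))
        for cid, chunks in sorted(per_cell.items())
    ]
    missed = sorted(set(vol.cell_ids().tolist()) - set(per_cell))
    return SparseStack(
        cells=cells, z_planes=z_planes, z_spacing=z_spacing, missed_cells=missed
    )


def generate_2d_elongated_tissue(
    n_cells: int = 200,
    domain: tuple[float, float] = (60.0, 250.0),
    voxel_size: tuple[float, float] = (0.2, 0.2),
    elongation_range: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> LabelVolume:
    """Seeded 2-D tissue of cells elongated along y (the longitudinal axis).

    Each cell's metric is ``diag(1, 1/e^2)`` with elongation ``e`` uniform
    in ``elongation_range``, so distances along y are discounted and the
    resulting regions stretch along y by about ``e``.  Site separation is
    tested in mean-elongation-stretched coordinates so longitudinal spacing
    grows proportionally.  Emulates a root-meristem longitudinal section.
    """
    emin, emax = elongation_range
    if n_cells < 2:
        raise ValidationError("need at least 2 cells")
    if not (emax >= emin >= 1.0):
        raise ValidationError("elongation_range must satisfy emax >= emin >= 1")
    rng = np.random.default_rng(seed)
    e_mean = 0.5 * (emin + emax)
    sites = _sample_sites(
        rng, n_cells, domain, min_separation, metric_scale=(1.0, e_mean)
    )
    entries = []
    for k in range(n_cells):
        e = rng.uniform(emin, emax)
        # Unit-determinant metric elongated along y by factor e.
        M = np.diag([e, 1.0 / e])
        entries.append((k + 1, Ellipsoid(center=sites[k], shape=M)))
    site_set = QuadraticSiteSet(entries=entries)

    dx, dy = voxel_size
    shape = (int(round(domain[1] / dy)), int(round(domain[0] / dx)))
    vol = LabelVolume(
        labels=np.zeros(shape, dtype=np.int32),
        voxel_size=voxel_size,
        truth_sites=site_set,
        seed=seed,
    )
    t = assign_quadratic(voxel_centers(vol), site_set)
    vol.labels = t.labels.reshape(shape).astype(np.int32)
    counts = np.bincount(vol.labels.ravel(), minlength=n_cells + 1)
    vol.truth_volumes = {
        cid: float(counts[cid]) * vol.voxel_volume for cid in range(1, n_cells + 1)
    }
    return vol


def slice_lines(
    vol: LabelVolume, y_spacing: float, seed: int = 0
) -> SparseStack:
    """Sample a 2-D tissue along sparse lines of constant y.

    The 2-D analogue of :func:`slice_phantom`: rows every ``y_spacing`` µm,
    and within each row every cell contributes the pixel centers whose
    left/right neighbor carries a different label (or the image border) —
    its wall crossings on that line.
    """
    if vol.dim != 2:
        raise ValidationError("slice_lines needs a 2-D volume")
    dx, dy = vol.voxel_size
    if y_spacing < dy:
        raise ValidationError(f"y_spacing {y_spacing} < voxel dy {dy}")
    rng = np.random.default_rng(seed)
    ny = vol.labels.shape[0]
    row_idx = _snap_planes(rng, ny * dy, y_spacing, dy)

    per_cell: dict[int, list[np.ndarray]] = {}
    y_lines = []
    for j in row_idx:
        row = vol.labels[j]
        y = (j + 0.5) * dy
        y_lines.append(y)
        padded = np.pad(row, 1, constant_values=-1)
        wall = (padded[:-2] != row) | (padded[2:] != row)
        ix = np.nonzero(wall)[0]
        labs = row[ix]
        x = (ix + 0.5) * dx
        for cid in np.unique(labs):
            if cid == 0:
                continue
            m = labs == cid
            pts = np.column_stack([x[m], np.full(int(m.sum()), y)])
            per_cell.setdefault(int(cid), []).append(pts)

    cells = [
        CellSliceSet(cell_id=cid, points=np.vstack(chunks))
        for cid, chunks in sorted(per_cell.items())
    ]
    missed = sorted(set(vol.cell_ids().tolist()) - set(per_cell))
    return SparseStack(
        cells=cells, z_planes=y_lines, z_spacing=y_spacing, missed_cells=missed
    )
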