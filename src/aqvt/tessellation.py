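"""Voronoi partitioning of a dense point cloud into cells.

Two diagrams are supported:

* the Euclidean Voronoi tessellation, where each cell is represented by a
  point site (the centroid of its sparse boundary samples), and
* the adaptive quadratic Voronoi tessellation (AQVT), where each cell k
  carries its own metric pair ``(c_k, M_k)`` estimated by fitting a
  minimum-volume enclosing ellipsoid to that cell's boundary samples, and a
  point x belongs to the region whose squared Mahalanobis distance
  ``(x - c_k)^T M_k (x - c_k)`` is smallest.

Bisectors of the quadratic diagram are quadratic hypersurfaces; assignment is
done by explicit distance evaluation against every site, which is exact and
deterministic (ties go to the smallest cell id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, ShapeError, ValidationError
from .mvee import Ellipsoid, fit_mvee

__all__ = [
    "CellSliceSet",
    "QuadraticSiteSet",
    "Tessellation",
    "estimate_centroid_sites",
    "fit_quadratic_sites",
    "assign_euclidean",
    "assign_quadratic",
    "cell_hulls",
]

_Z_DISTINCT_TOL = 1e-6


@dataclass
class CellSliceSet:
    """Sparse boundary samples of one tracked cell, pooled over its slices."""

    cell_id: int
    points: np.ndarray  # (n, d) in µm
    n_slices: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ShapeError("points must be (n, d)")
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.n_slices == 0 and self.points.size:
            # Distinct z-planes (last coordinate) represented in the samples.
            z = np.sort(self.points[:, -1])
            self.n_slices = 1 + int(np.sum(np.diff(z) > _Z_DISTINCT_TOL))

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class QuadraticSiteSet:
    """Ordered (cell_id, Ellipsoid) pairs parameterizing a quadratic diagram."""

    entries: list[tuple[int, Ellipsoid]]
    degenerate_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate cell_ids in site set")
        dims = {e.dim for _, e in self.entries}
        if len(dims) > 1:
            raise ShapeError(f"mixed ellipsoid dimensions: {sorted(dims)}")

    @property
    def dim(self) -> int:
        return self.entries[0][1].dim

    @property
    def cell_ids(self) -> list[int]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, cell_id: int) -> Ellipsoid:
        for cid, e in self.entries:
            if cid == cell_id:
                return e
        raise KeyError(cell_id)


@dataclass
class Tessellation:
    """A labeled dense point cloud: the reconstructed tissue."""

    cloud: np.ndarray  # (N, d) µm
    labels: np.ndarray  # (N,) int cell ids
    site_set: object  # QuadraticSiteSet or list of (cell_id, point)
    per_cell_volume: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.labels.shape[0] != self.cloud.shape[0]:
            raise ShapeError("labels length must equal cloud length")

    def counts(self) -> dict[int, int]:
        ids, cts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), cts.tolist()))

    def volumes_from_counts(self, point_volume: float) -> dict[int, float]:
        """Per-cell volume as assigned-point count x lattice cell volume."""
        return {cid: ct * point_volume for cid, ct in self.counts().items()}


def estimate_centroid_sites(cells: list[CellSliceSet]) -> list[tuple[int, np.ndarray]]:
    """Arithmetic-mean site per cell, order preserved.

    The centroid of a cell's pooled boundary samples approximates the
    nucleus position used as a Voronoi site when nuclei are not imaged.
    """
    sites = []
    for cell in cells:
        if len(cell) == 0:
            raise ValidationError(f"cell {cell.cell_id} has no points")
        sites.append((cell.cell_id, cell.points.mean(axis=0)))
    return sites


def _jitter_degenerate(points: np.ndarray, plane_epsilon: float) -> np.ndarray:
    """Symmetrically extrude a rank-deficient point set along its null axes."""
    d = points.shape[1]
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=True)
    svals = np.concatenate([svals, np.zeros(d - svals.size)])
    scale = svals[0] if svals[0] > 0 else 1.0
    deficient = [vt[i] for i in range(d) if svals[i] <= 1e-9 * scale]
    out = [points]
    for v in deficient:
        out.append(points + plane_epsilon * v)
        out.append(points - plane_epsilon * v)
    return np.vstack(out)


def fit_quadratic_sites(
    cells: list[CellSliceSet],
    tol: float = 1e-4,
    plane_epsilon: float = 0.3,
) -> QuadraticSiteSet:
    """Estimate each cell's (c_k, M_k) by MVEE of its own boundary points.

    Cells whose samples affinely span the full dimension are fitted
    directly.  Rank-deficient cells (typically seen in a single slice, so
    all samples share one z) are symmetrically extruded by
    ``+-plane_epsilon`` µm along each deficient axis before fitting, and
    flagged in ``degenerate_ids``.
    """
    entries: list[tuple[int, Ellipsoid]] = []
    degenerate: set[int] = set()
    for cell in cells:
        if len(cell) == 0:
            raise ValidationError(f"cell {cell.cell_id} has no points")
        pts = cell.points
        d = pts.shape[1]
        try:
            res = fit_mvee(pts, tol=tol)
        except DegenerateGeometryError:
            pts = _jitter_degenerate(pts, plane_epsilon)
            if pts.shape[0] < d + 1:
                raise ValidationError(
                    f"cell {cell.cell_id}: only {pts.shape[0]} points after "
                    f"jittering, need at least {d + 1}"
                )
            res = fit_mvee(pts, tol=tol)
            degenerate.add(cell.cell_id)
        entries.append((cell.cell_id, res.ellipsoid))
    return QuadraticSiteSet(entries=entries, degenerate_ids=frozenset(degenerate))


def _check_cloud(cloud: np.ndarray, dim: int) -> np.ndarray:
    X = np.asarray(cloud, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("cloud must be a non-empty (N, d) array")
    if X.shape[1] != dim:
        raise ShapeError(f"cloud dimension {X.shape[1]} != site dimension {dim}")
    return X


def assign_euclidean(
    cloud,
    sites: list[tuple[int, np.ndarray]],
    point_volume: float | None = None,
) -> Tessellation:
    """Label each cloud point with the nearest site under Euclidean distance.

    Ties at bisectors are broken toward the smallest cell id so that the
    labeling is a total partition.
    """
    if not sites:
        raise ValidationError("need at least one site")
    order = sorted(range(len(sites)), key=lambda i: sites[i][0])
    ids = np.array([sites[i][0] for i in order])
    C = np.array([np.asarray(sites[i][1], dtype=float) for i in order])
    if np.unique(np.round(C, 12), axis=0).shape[0] != C.shape[0]:
        raise ValidationError("duplicate site coordinates: partition ambiguous")
    X = _check_cloud(cloud, C.shape[1])
    best = np.full(X.shape[0], np.inf)
    lab = np.zeros(X.shape[0], dtype=ids.dtype)
    for k in range(C.shape[0]):
        diff = X - C[k]
        dist = np.einsum("ij,ij->i", diff, diff)
        take = dist < best  # strict: first (smallest id) wins ties
        best[take] = dist[take]
        lab[take] = ids[k]
    t = Tessellation(cloud=X, labels=lab, site_set=list(sites))
    if point_volume is not None:
        t.per_cell_volume = t.volumes_from_counts(point_volume)
    return t


def assign_quadratic(
    cloud,
    sites: QuadraticSiteSet,
    point_volume: float | None = None,
) -> Tessellation:
    """Label each cloud point by its quadratic-nearest site.

    Point x goes to ``argmin_k (x - c_k)^T M_k (x - c_k)``; ties to the
    smallest cell id.  Scaling every ``M_k`` by a common positive scalar
    leaves the labeling unchanged.
    """
    if len(sites) == 0:
        raise ValidationError("need at least one site")
    order = sorted(range(len(sites)), key=lambda i: sites.entries[i][0])
    ids = np.array([sites.entries[i][0] for i in order])
    X = _check_cloud(cloud, sites.dim)
    best = np.full(X.shape[0], np.inf)
    lab = np.zeros(X.shape[0], dtype=ids.dtype)
    for k, i in enumerate(order):
        e = sites.entries[i][1]
        diff = X - e.center
        dist = np.einsum("ij,jk,ik->i", diff, e.shape, diff)
        take = dist < best
        best[take] = dist[take]
        lab[take] = ids[k]
    t = Tessellation(cloud=X, labels=lab, site_set=sites)
    if point_volume is not None:
        t.per_cell_volume = t.volumes_from_counts(point_volume)
    return t


def cell_hulls(t: Tessellation):
    """Convex-hull mesh and volume per cell.

    Returns ``(meshes, failures)`` where ``meshes`` maps cell_id to a dict
    with ``vertices`` (V, 3), ``faces`` (F, 3) and ``volume`` (µm^3), and
    ``failures`` maps cell_id to the reason its hull could not be built
    (fewer than 4 points, or a degenerate/coplanar point set).
    """
    import trimesh

    meshes: dict[int, dict] = {}
    failures: dict[int, str] = {}
    for cid in np.unique(t.labels).tolist():
        pts = t.cloud[t.labels == cid]
        if pts.shape[0] < 4:
            failures[cid] = f"only {pts.shape[0]} assigned points"
            continue
        try:
            hull = trimesh.Trimesh(vertices=pts, process=False).convex_hull
        except Exception as exc:  # qhull degenerate input
            failures[cid] = f"hull failed: {exc}"
            continue
        if hull.volume <= 0:
            failures[cid] = "degenerate (zero-volume) hull"
            continue
        meshes[cid] = {
            "vertices": np.asarray(hull.vertices),
            "faces": np.asarray(hull.faces),
            "volume": float(hull.volume),
        }
    return meshes, failures
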