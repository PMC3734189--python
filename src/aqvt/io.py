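"""File I/O: point CSVs, TIFF label stacks with JSON sidecars, PLY meshes.

All coordinates in file payloads are physical µm; label arrays live in index
space with voxel-size metadata in a JSON sidecar, and the conversion happens
exactly once at this boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import AqvtError, ParseError, ValidationError
from .mvee import Ellipsoid
from .phantom import LabelVolume, SparseStack
from .tessellation import CellSliceSet, QuadraticSiteSet

__all__ = [
    "RunConfig",
    "read_cell_points_csv",
    "write_cell_points_csv",
    "read_label_stack",
    "write_label_stack",
    "write_meshes",
]

_CSV_COLUMNS = ["cell_id", "x", "y", "z"]


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one reconstruction run."""

    points_path: str | None = None
    stack_path: str | None = None
    output_dir: str = "."
    voxel_size: tuple[float, ...] = (0.2, 0.2, 0.225)
    mvee_tol: float = 1e-4
    plane_epsilon: float = 0.3
    surface_grid: tuple[int, int] = (64, 64)
    surface_smoothness: float = 1e-3
    cloud_spacing: tuple[float, ...] | None = None
    method: str = "aqvt"
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("euclidean", "aqvt"):
            raise ValidationError(f"method must be euclidean or aqvt, got {self.method!r}")
        for name in ("mvee_tol", "plane_epsilon", "surface_smoothness"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size entries must be positive")

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("voxel_size", "surface_grid", "cloud_spacing"):
            if payload[key] is not None:
                payload[key] = list(payload[key])
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("voxel_size", "surface_grid", "cloud_spacing"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def read_cell_points_csv(path) -> list[CellSliceSet]:
    """Read per-cell boundary points from a ``cell_id,x,y,z`` CSV (µm).

    Rows are grouped by ``cell_id`` (order-independent); a cell's slice
    count is the number of distinct z values it carries.  A ``cell_id,x,y``
    header is accepted for 2-D data.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    cols = [c.strip() for c in df.columns]
    coord_cols = _CSV_COLUMNS[1:] if "z" in cols else _CSV_COLUMNS[1:3]
    for col in ["cell_id"] + coord_cols:
        if col not in cols:
            raise ParseError(f"{path}: missing column {col!r} (have {cols})")
    df.columns = cols
    numeric = df[["cell_id"] + coord_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
        raise ParseError(f"{path}: non-numeric value at line {line}")
    # Re-parse coordinates with numpy's correctly-rounded strtod so the
    # write -> read round trip is bit-exact.
    for col in coord_cols:
        numeric[col] = df[col].to_numpy(dtype=float)
    cells = []
    for cid, group in numeric.groupby("cell_id", sort=True):
        cells.append(
            CellSliceSet(
                cell_id=int(cid), points=group[coord_cols].to_numpy(dtype=float)
            )
        )
    return cells


def write_cell_points_csv(cells, path) -> None:
    """Write cells (a list of CellSliceSet or a SparseStack) to CSV."""
    if isinstance(cells, SparseStack):
        cells = cells.cells
    frames = []
    for cell in cells:
        d = cell.points.shape[1]
        cols = _CSV_COLUMNS[1 : 1 + d]
        frame = pd.DataFrame(cell.points, columns=cols)
        frame.insert(0, "cell_id", cell.cell_id)
        frames.append(frame)
    # %.17g keeps the round trip bit-exact for doubles
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def _sites_to_payload(sites: QuadraticSiteSet) -> list[dict]:
    return [
        {
            "cell_id": int(cid),
            "center": e.center.tolist(),
            "shape": e.shape.tolist(),
        }
        for cid, e in sites.entries
    ]


def _sites_from_payload(payload) -> QuadraticSiteSet:
    entries = [
        (
            int(item["cell_id"]),
            Ellipsoid(
                center=np.array(item["center"]), shape=np.array(item["shape"])
            ),
        )
        for item in payload
    ]
    return QuadraticSiteSet(entries=entries)


def write_label_stack(vol: LabelVolume, path, sidecar_path=None) -> None:
    """Write a label volume as a multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.labels.astype(np.int32), photometric="minisblack")
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    payload = {
        "voxel_size": list(vol.voxel_size),
        "seed": vol.seed,
        "truth_volumes": {str(k): v for k, v in vol.truth_volumes.items()},
    }
    if vol.truth_sites is not None:
        payload["truth_sites"] = _sites_to_payload(vol.truth_sites)
    Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def read_label_stack(path, sidecar=None, voxel_size=None) -> LabelVolume:
    """Read a multi-page TIFF label stack and its JSON sidecar.

    The sidecar provides ``voxel_size`` (µm) and, for phantoms, the truth
    sites and volumes; without a sidecar ``voxel_size`` must be supplied.
    """
    path = Path(path)
    try:
        labels = tifffile.imread(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    if labels.dtype == object:
        raise ParseError(f"{path}: inconsistent page shapes")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ParseError(f"{path}: expected integer labels, got {labels.dtype}")
    if sidecar is None:
        candidate = path.with_suffix(".json")
        sidecar = candidate if candidate.exists() else None
    truth_sites = None
    truth_volumes = {}
    seed = None
    if sidecar is not None:
        payload = json.loads(Path(sidecar).read_text())
        voxel_size = tuple(payload["voxel_size"])
        seed = payload.get("seed")
        truth_volumes = {
            int(k): float(v) for k, v in payload.get("truth_volumes", {}).items()
        }
        if "truth_sites" in payload:
            truth_sites = _sites_from_payload(payload["truth_sites"])
    if voxel_size is None:
        raise ParseError(
            f"{path}: no sidecar found; voxel_size must be given explicitly"
        )
    return LabelVolume(
        labels=labels,
        voxel_size=tuple(voxel_size),
        truth_sites=truth_sites,
        truth_volumes=truth_volumes,
        seed=seed,
    )


def write_meshes(meshes: dict[int, dict], out_dir) -> Path:
    """Write per-cell convex hulls as ASCII PLY files plus a manifest CSV.

    ``meshes`` maps cell_id to ``{"vertices", "faces", "volume"}`` as
    returned by :func:`aqvt.tessellation.cell_hulls`.  Returns the manifest
    path; manifest rows are (cell_id, n_vertices, n_faces, volume_um3).
    """
    import trimesh

    if not meshes:
        raise ValidationError("mesh map is empty")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise AqvtError(f"cannot create output dir {out_dir}: {exc}") from None
    rows = []
    for cid in sorted(meshes):
        m = meshes[cid]
        mesh = trimesh.Trimesh(
            vertices=m["vertices"], faces=m["faces"], process=False
        )
        ply_path = out_dir / f"cell_{cid:05d}.ply"
        ply_path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
        rows.append(
            {
                "cell_id": cid,
                "n_vertices": int(mesh.vertices.shape[0]),
                "n_faces": int(mesh.faces.shape[0]),
                "volume_um3": m["volume"],
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
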