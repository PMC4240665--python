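"""Reading and validating triangulated surface meshes of scanned specimens.

A specimen here is the scanned face of a stone (a hammerstone, a naturally
abraded cobble, or an archaeological piece). Meshes are treated as open
surface patches in millimetres; unit metadata inside files is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "GROUP_LABELS",
    "SurfaceMesh",
    "EmptyMeshError",
    "read_mesh",
    "write_mesh",
    "median_vertex_spacing",
    "read_manifest",
]

log = logging.getLogger(__name__)

#: Recognised specimen group labels (free-form labels elsewhere fall back to
#: "unknown" at the mesh level; the statistics layer is label-agnostic).
GROUP_LABELS = ("experimental", "natural", "archaeological", "unknown")

_DEGENERATE_AREA = 1e-12  # mm^2; faces below this are dropped


class EmptyMeshError(ValueError):
    """Raised when a mesh has no valid faces after cleaning."""


@dataclass(frozen=True)
class SurfaceMesh:
    """A validated triangulated surface patch.

    Attributes
    ----------
    vertices : (n, 3) float array, coordinates in mm.
    faces : (m, 3) int array of vertex indices.
    specimen_id : identifier used in downstream tables.
    group_label : one of :data:`GROUP_LABELS`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    specimen_id: str = "unknown"
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError("vertices must be an (n>=3, 3) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("mesh contains non-finite vertex coordinates")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 1:
            raise ValueError("faces must be an (m>=1, 3) array")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("face references out-of-range vertex index")
        if np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise ValueError("face references a repeated vertex index")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.group_label not in GROUP_LABELS:
            object.__setattr__(self, "group_label", "unknown")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        """Triangle areas in mm^2."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _clean_faces(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, int]:
    """Drop degenerate (zero-area or repeated-index) faces; return kept faces
    and the number dropped."""
    faces = np.asarray(faces, dtype=np.int64)
    if faces.size == 0:
        return faces.reshape(0, 3), 0
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    keep = distinct & (areas > _DEGENERATE_AREA)
    n_dropped = int((~keep).sum())
    return faces[keep], n_dropped


def read_mesh(
    path: str | Path,
    fmt: str = "auto",
    specimen_id: str | None = None,
    group_label: str = "unknown",
) -> SurfaceMesh:
    """Read a PLY/OBJ/STL mesh and validate it as a surface patch.

    Degenerate faces are dropped (count logged). Coordinates are assumed to
    be in millimetres regardless of any unit metadata in the file.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    file_type = None if fmt == "auto" else fmt
    try:
        loaded = trimesh.load(str(path), file_type=file_type, process=False)
    except Exception as exc:  # noqa: BLE001 - wrap loader failures uniformly
        raise IOError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"no geometry in {path}")
        loaded = trimesh.util.concatenate(geoms)
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    faces, n_dropped = _clean_faces(vertices, faces)
    if n_dropped:
        log.info("%s: dropped %d degenerate face(s)", path.name, n_dropped)
    if len(faces) == 0:
        raise EmptyMeshError(f"no valid faces after cleaning: {path}")
    return SurfaceMesh(
        vertices=vertices,
        faces=faces,
        specimen_id=specimen_id if specimen_id is not None else path.stem,
        group_label=group_label,
    )


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write the mesh (format from the file extension: .ply/.obj/.stl)."""
    path = Path(path)
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    )
    tm.export(str(path))
    return path


def median_vertex_spacing(mesh: SurfaceMesh) -> float:
    """Median length over all unique triangle edges, in mm.

    Used as the default DEM cell size: it reflects the information content
    of the scan.
    """
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    edges = np.unique(edges, axis=0)
    d = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    spacing = float(np.median(d))
    if not spacing > 0:
        raise ValueError("median vertex spacing is not positive")
    return spacing


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a specimen manifest (delimited text, columns: specimen_id, path,
    group_label). Paths are resolved relative to the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"specimen_id", "path", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]
    ]
    return df
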