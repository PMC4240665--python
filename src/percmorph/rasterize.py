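"""TIN-to-raster conversion: micro-DEMs from triangulated surface patches.

The mesh is projected along one coordinate axis onto a regular grid and the
elevation at each cell centre is obtained by barycentric (linear)
interpolation within the covering triangle — the standard linear
TIN-to-raster rule. Where a folded or closed mesh covers a cell centre with
several triangles, the triangle nearest the viewer (largest height toward
the viewer) wins, which makes the rule deterministic without pre-cropping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .mesh_io import SurfaceMesh, median_vertex_spacing

__all__ = [
    "ElevationRaster",
    "RasterTooCoarseError",
    "DegenerateProjectionError",
    "rasterize_tin",
    "default_projection_axis",
    "write_ascii_grid",
    "read_ascii_grid",
]

log = logging.getLogger(__name__)

#: projection axis -> (coordinate index, sign toward the viewer)
_AXES = {
    "+x": (0, 1.0),
    "-x": (0, -1.0),
    "+y": (1, 1.0),
    "-y": (1, -1.0),
    "+z": (2, 1.0),
    "-z": (2, -1.0),
}

NODATA = -9999.0


class RasterTooCoarseError(ValueError):
    """cell_size so large that fewer than 25 cells would result."""


class DegenerateProjectionError(ValueError):
    """Mesh is entirely perpendicular to the projection plane."""


@dataclass
class ElevationRaster:
    """Regular-grid micro-DEM with a nodata mask.

    ``z[0, 0]`` is the top-left (north-west) cell; ``origin`` is the
    lower-left corner of the grid in the projection plane. Elevations are in
    mm, measured toward the viewer along ``projection_axis``.
    """

    z: np.ndarray
    nodata_mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    projection_axis: str = "+z"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.z.ndim != 2 or self.z.shape != self.nodata_mask.shape:
            raise ValueError("z and nodata_mask must be equal 2-D shapes")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.projection_axis not in _AXES:
            raise ValueError(f"unknown projection axis {self.projection_axis}")
        if not np.all(np.isfinite(self.z[~self.nodata_mask])):
            raise ValueError("unmasked cells must be finite")

    @property
    def n_rows(self) -> int:
        return self.z.shape[0]

    @property
    def n_cols(self) -> int:
        return self.z.shape[1]

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Planar (x, y) mm coordinates of cell centres."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - 1 - np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def copy_with(self, **kw) -> "ElevationRaster":
        return replace(self, **kw)


def default_projection_axis(mesh: SurfaceMesh) -> str:
    """Axis of smallest bounding-box extent (the surface-normal direction
    for a roughly planar patch), positive orientation."""
    extents = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    return "+" + "xyz"[int(np.argmin(extents))]


def rasterize_tin(
    mesh: SurfaceMesh,
    cell_size: float | None = None,
    projection_axis: str | None = None,
) -> ElevationRaster:
    """Linear (barycentric) TIN-to-raster interpolation at cell centres.

    Parameters
    ----------
    cell_size : grid pitch in mm; defaults to the mesh's median vertex
        spacing.
    projection_axis : one of ``+x,-x,+y,-y,+z,-z``; defaults to the axis of
        smallest bounding-box extent.
    """
    if projection_axis is None:
        projection_axis = default_projection_axis(mesh)
    if cell_size is None:
        cell_size = median_vertex_spacing(mesh)
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    k, sign = _AXES[projection_axis]
    iu, iv = [i for i in range(3) if i != k]

    u = mesh.vertices[:, iu]
    v = mesh.vertices[:, iv]
    h = sign * mesh.vertices[:, k]

    x0, y0 = float(u.min()), float(v.min())
    n_cols = max(1, int(math.ceil((u.max() - x0) / cell_size)))
    n_rows = max(1, int(math.ceil((v.max() - y0) / cell_size)))
    if n_rows * n_cols < 25:
        raise RasterTooCoarseError(
            f"cell_size {cell_size} yields only {n_rows * n_cols} cells (<25)"
        )

    best = np.full((n_rows, n_cols), -np.inf)
    area_tol = 1e-12 * cell_size * cell_size
    any_face = False
    tri_u = u[mesh.faces]
    tri_v = v[mesh.faces]
    tri_h = h[mesh.faces]

    for fi in range(len(mesh.faces)):
        ua, ub, uc = tri_u[fi]
        va, vb, vc = tri_v[fi]
        det = (ub - ua) * (vc - va) - (uc - ua) * (vb - va)
        if abs(det) <= area_tol:
            continue  # edge-on triangle: no projected area
        any_face = True
        # candidate cell centres inside the triangle's bbox
        cmin = max(0, int(math.floor((min(ua, ub, uc) - x0) / cell_size - 0.5)))
        cmax = min(
            n_cols - 1, int(math.ceil((max(ua, ub, uc) - x0) / cell_size - 0.5))
        )
        rlo = (min(va, vb, vc) - y0) / cell_size - 0.5
        rhi = (max(va, vb, vc) - y0) / cell_size - 0.5
        rmin = max(0, int(math.floor(n_rows - 1 - rhi)))
        rmax = min(n_rows - 1, int(math.ceil(n_rows - 1 - rlo)))
        if cmin > cmax or rmin > rmax:
            continue
        cols = np.arange(cmin, cmax + 1)
        rows = np.arange(rmin, rmax + 1)
        px = x0 + (cols + 0.5) * cell_size
        py = y0 + (n_rows - 1 - rows + 0.5) * cell_size
        PX, PY = np.meshgrid(px, py)
        # barycentric coordinates wrt (a, b, c)
        l1 = ((PX - ua) * (vc - va) - (uc - ua) * (PY - va)) / det
        l2 = ((ub - ua) * (PY - va) - (PX - ua) * (vb - va)) / det
        l0 = 1.0 - l1 - l2
        tol = -1e-12
        inside = (l0 >= tol) & (l1 >= tol) & (l2 >= tol)
        if not inside.any():
            continue
        ha, hb, hc = tri_h[fi]
        zc = l0 * ha + l1 * hb + l2 * hc
        sub = best[rmin : rmax + 1, cmin : cmax + 1]
        np.copyto(sub, zc, where=inside & (zc > sub))

    if not any_face:
        raise DegenerateProjectionError(
            "mesh projects to zero area along " + projection_axis
        )
    mask = ~np.isfinite(best)
    if mask.all():
        raise DegenerateProjectionError("no cell centre covered by any triangle")
    z = np.where(mask, 0.0, best)
    return ElevationRaster(
        z=z,
        nodata_mask=mask,
        origin=(x0, y0),
        cell_size=float(cell_size),
        projection_axis=projection_axis,
    )


def write_ascii_grid(raster: ElevationRaster, path: str | Path) -> Path:
    """Export as an ESRI ASCII grid for inspection in GIS software."""
    path = Path(path)
    x0, y0 = raster.origin
    lines = [
        f"ncols {raster.n_cols}",
        f"nrows {raster.n_rows}",
        f"xllcorner {x0:.6f}",
        f"yllcorner {y0:.6f}",
        f"cellsize {raster.cell_size:.6f}",
        f"NODATA_value {NODATA:.1f}",
    ]
    body = np.where(raster.nodata_mask, NODATA, raster.z)
    for row in body:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ascii_grid(
    path: str | Path, projection_axis: str = "+z"
) -> ElevationRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    z = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    if z.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid body shape mismatch in {path}")
    mask = z == nodata
    return ElevationRaster(
        z=np.where(mask, 0.0, z),
        nodata_mask=mask,
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        cell_size=header["cellsize"],
        projection_axis=projection_axis,
    )
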