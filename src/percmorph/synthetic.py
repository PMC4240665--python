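"""Synthetic cobble-surface simulator with ground-truth damage masks.

Two damage morphologies are contrasted, mirroring the qualitative
distinction between fluvial abrasion and percussive use-wear on
fine-grained igneous cobbles:

* **natural** — smooth Gaussian-profile cupules (rounded perimeters,
  deep smooth bases, blending tangentially into the surface) together
  with smooth rounded bosses, the high knobs that rolling abrasion leaves
  standing proud of the surface;
* **anthropogenic** — patches of crushed texture: a correlated
  ridge-and-hollow bed whose hollows are damped (crushed debris partly
  fills them, which is why percussive pits rarely form coherent cold
  spots), overlaid with sharp sub-cell peaks and shallow notches, on a
  faint smoothed basin.

Both classes share an identical undamaged base surface (a low-frequency
convex dome emulating a water-worn cobble, a faint correlated polish
texture and uncorrelated scanner measurement noise), so any downstream
detection difference is attributable to damage morphology alone. Each
surface comes with a boolean mask of truly damaged cells, enabling
sensitivity/specificity measurement of the whole pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasterize import ElevationRaster, write_ascii_grid

__all__ = [
    "SyntheticSurfaceParams",
    "generate_surface",
    "generate_benchmark",
    "raster_to_mesh",
]

log = logging.getLogger(__name__)

DAMAGE_CLASSES = ("natural", "anthropogenic", "undamaged")


@dataclass(frozen=True)
class SyntheticSurfaceParams:
    """Parameters of one synthetic surface. All lengths in mm.

    Defaults describe a 15 x 15 mm scanned patch at 0.1 mm pitch (within
    typical laser-scanner point densities for such specimens). The
    undamaged texture is dominated by uncorrelated scanner measurement
    noise (s.d. 8 µm) over a faint correlated polish texture (s.d. 0.8 µm,
    correlation length 0.2 mm) on a 1 mm dome.

    Natural damage: ``n_features`` cupules of footprint radius
    ``feature_radius`` and depth ``natural_pit_depth`` (uniform draws),
    plus ``natural_boss_count`` rounded bosses (spherical caps) of radius
    ``natural_boss_radius`` and height ``natural_boss_height``.

    Anthropogenic damage: ``n_features`` circular patches of radius
    ``anthro_patch_radius``, each carrying a correlated ridge bed
    (amplitude ``anthro_ridge_sd``, correlation length
    ``anthro_ridge_corr``, hollows damped by ``anthro_hollow_damping``),
    sharp peaks (half-normal, scale ``anthro_peak_height_sd``) and shallow
    notches (scale ``anthro_notch_depth_sd``) of footprint sigma
    ``anthro_peak_sigma`` at ``anthro_peak_density`` per mm^2, over a
    smoothed basin of depth ``anthro_basin_depth``.
    """

    n_rows: int = 150
    n_cols: int = 150
    cell_size: float = 0.1
    base_dome_height: float = 1.0
    base_noise_sd: float = 0.0008
    base_noise_corr: float = 0.2
    scanner_noise_sd: float = 0.008
    damage_class: str = "undamaged"
    n_features: int = 3
    # natural class
    feature_radius: tuple[float, float] = (2.0, 2.6)
    natural_pit_depth: tuple[float, float] = (0.6, 0.9)
    rim_smoothing: float = 0.3
    natural_boss_count: int = 5
    natural_boss_radius: tuple[float, float] = (0.5, 0.8)
    natural_boss_height: tuple[float, float] = (0.18, 0.28)
    # anthropogenic class
    anthro_patch_radius: float = 2.0
    anthro_basin_depth: float = 0.05
    anthro_ridge_sd: float = 0.04
    anthro_ridge_corr: float = 0.25
    anthro_hollow_damping: float = 0.2
    anthro_peak_density: float = 8.0  # peaks+notches per mm^2
    anthro_peak_height_sd: float = 0.08
    anthro_notch_depth_sd: float = 0.025
    anthro_peak_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.damage_class not in DAMAGE_CLASSES:
            raise ValueError(f"unknown damage_class {self.damage_class!r}")
        for name in (
            "cell_size",
            "base_dome_height",
            "base_noise_sd",
            "base_noise_corr",
            "rim_smoothing",
            "anthro_patch_radius",
            "anthro_ridge_sd",
            "anthro_ridge_corr",
            "anthro_peak_height_sd",
            "anthro_notch_depth_sd",
            "anthro_peak_sigma",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.anthro_peak_density < 0:
            raise ValueError("anthro_peak_density must be >= 0")
        if self.scanner_noise_sd < 0:
            raise ValueError("scanner_noise_sd must be >= 0")
        if not 0 <= self.anthro_hollow_damping <= 1:
            raise ValueError("anthro_hollow_damping must be in [0, 1]")
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid must be at least 10 x 10")


def _base_surface(p: SyntheticSurfaceParams, rng: np.random.Generator):
    """Dome + correlated polish texture + scanner noise (all classes)."""
    cs = p.cell_size
    y = (np.arange(p.n_rows)[:, None] + 0.5) * cs
    x = (np.arange(p.n_cols)[None, :] + 0.5) * cs
    cx, cy = p.n_cols * cs / 2.0, p.n_rows * cs / 2.0
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    rmax2 = cx**2 + cy**2
    dome = p.base_dome_height * (1.0 - r2 / rmax2)
    smooth = ndimage.gaussian_filter(
        rng.standard_normal((p.n_rows, p.n_cols)),
        sigma=p.base_noise_corr / cs,
    )
    sd = smooth.std()
    texture = smooth * (p.base_noise_sd / sd) if sd > 0 else smooth
    scanner = rng.normal(0.0, p.scanner_noise_sd, (p.n_rows, p.n_cols))
    return dome + texture + scanner, x, y


def _feature_center(
    rng: np.random.Generator, radius: float, width: float, height: float
):
    """Random centre keeping the feature inside the extent where possible;
    oversized features are centred and clipped (logged)."""
    if 2 * radius > min(width, height):
        log.info("feature radius %.2f mm exceeds grid; clipped", radius)
    lo_x, hi_x = min(radius, width / 2), max(width - radius, width / 2)
    lo_y, hi_y = min(radius, height / 2), max(height - radius, height / 2)
    return rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)


def _spherical_cap(depth: float, radius: float, rho2: np.ndarray) -> np.ndarray:
    """Height profile of a spherical cap (base radius, apex height) at
    squared planar distance rho2; zero outside the base circle."""
    R = (radius**2 + depth**2) / (2.0 * depth)
    inside = rho2 <= radius**2
    prof = np.zeros_like(rho2)
    prof[inside] = np.sqrt(R**2 - rho2[inside]) - (R - depth)
    return prof


def _add_natural(p, rng, z, x, y, mask):
    cs = p.cell_size
    w, h = p.n_cols * cs, p.n_rows * cs
    for _ in range(p.n_features):
        r = rng.uniform(*p.feature_radius)
        d = rng.uniform(*p.natural_pit_depth)
        cx, cy = _feature_center(rng, r, w, h)
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        # Gaussian profile: tangential blend, rounded rim, smooth deep base
        z = z - d * np.exp(-rho2 / (2.0 * (r / 2.0) ** 2))
        mask |= rho2 <= r * r
    for _ in range(p.natural_boss_count):
        r = rng.uniform(*p.natural_boss_radius)
        hb = rng.uniform(*p.natural_boss_height)
        cx, cy = _feature_center(rng, r, w, h)
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        z = z + _spherical_cap(hb, r, rho2)
        mask |= rho2 <= r * r
    return z


def _add_anthropogenic(p, rng, z, x, y, mask):
    cs = p.cell_size
    w, h = p.n_cols * cs, p.n_rows * cs
    basin = np.zeros_like(z)
    for _ in range(p.n_features):
        r = p.anthro_patch_radius
        cx, cy = _feature_center(rng, r, w, h)
        rho2 = (x - cx) ** 2 + (y - cy) ** 2
        rho = np.sqrt(rho2)
        mask |= rho2 <= r * r
        if p.anthro_basin_depth > 0:
            basin += _spherical_cap(p.anthro_basin_depth, r, rho2)
        # crushed ridge-and-hollow bed, hollows damped, tapered at the edge
        g = ndimage.gaussian_filter(
            rng.standard_normal(z.shape), sigma=p.anthro_ridge_corr / cs
        )
        g /= g.std()
        ridge = np.where(g > 0, g, p.anthro_hollow_damping * g)
        ridge *= p.anthro_ridge_sd
        taper = np.clip((r - rho) / (3 * cs), 0.0, 1.0)
        z = z + ridge * taper
        # sharp peaks and shallow notches, sub-cell footprint
        n_spk = rng.poisson(p.anthro_peak_density * np.pi * r * r)
        rad = r * np.sqrt(rng.uniform(size=n_spk))
        theta = rng.uniform(0, 2 * np.pi, size=n_spk)
        sx, sy = cx + rad * np.cos(theta), cy + rad * np.sin(theta)
        is_peak = rng.uniform(size=n_spk) < 0.5
        amp = np.where(
            is_peak,
            np.abs(rng.normal(0.0, p.anthro_peak_height_sd, n_spk)),
            -np.abs(rng.normal(0.0, p.anthro_notch_depth_sd, n_spk)),
        )
        sig = p.anthro_peak_sigma
        half = max(1, int(np.ceil(3 * sig / cs)))
        for k in range(n_spk):
            ci, cj = int(sy[k] / cs), int(sx[k] / cs)
            i0, i1 = max(0, ci - half), min(p.n_rows, ci + half + 1)
            j0, j1 = max(0, cj - half), min(p.n_cols, cj + half + 1)
            if i0 >= i1 or j0 >= j1:
                continue
            d2 = (x[0, j0:j1][None, :] - sx[k]) ** 2 + (
                y[i0:i1, 0][:, None] - sy[k]
            ) ** 2
            z[i0:i1, j0:j1] += amp[k] * np.exp(-d2 / (2 * sig * sig))
    z = z - ndimage.gaussian_filter(basin, sigma=3 * p.rim_smoothing / cs)
    return z


def generate_surface(
    p: SyntheticSurfaceParams,
) -> tuple[ElevationRaster, np.ndarray]:
    """Generate one surface; returns (raster, ground-truth damage mask).

    Same parameters + seed always produce bit-identical output.
    """
    rng = np.random.default_rng(p.seed)
    z, x, y = _base_surface(p, rng)
    mask = np.zeros(z.shape, dtype=bool)
    if p.damage_class == "natural" and p.n_features > 0:
        z = _add_natural(p, rng, z, x, y, mask)
    elif p.damage_class == "anthropogenic" and p.n_features > 0:
        z = _add_anthropogenic(p, rng, z, x, y, mask)
    raster = ElevationRaster(
        z=z,
        nodata_mask=np.zeros(z.shape, dtype=bool),
        origin=(0.0, 0.0),
        cell_size=p.cell_size,
        projection_axis="+z",
    )
    return raster, mask


def raster_to_mesh(raster: ElevationRaster):
    """Triangulate a full raster into a SurfaceMesh (two triangles per
    cell quad) — used to exercise the mesh and TIN-rasterization stages on
    synthetic surfaces."""
    from .mesh_io import SurfaceMesh

    nr, nc = raster.n_rows, raster.n_cols
    rows, cols = np.mgrid[0:nr, 0:nc]
    xs, ys = raster.cell_center(rows.ravel(), cols.ravel())
    verts = np.column_stack([xs, ys, raster.z.ravel()])
    idx = np.arange(nr * nc).reshape(nr, nc)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([b, d, c])]
    )
    return SurfaceMesh(vertices=verts, faces=faces)


def generate_benchmark(
    out_dir: str | Path | None,
    n_per_class: int = 20,
    classes: tuple[str, ...] = ("anthropogenic", "natural"),
    params_by_class: dict[str, SyntheticSurfaceParams] | None = None,
    seed: int = 1,
    write_masks: bool = True,
    write_meshes: bool = False,
) -> pd.DataFrame:
    """Generate a labelled benchmark of synthetic surfaces.

    With ``out_dir`` set, surfaces are written as ESRI ASCII grids (plus
    optional ground-truth masks and PLY meshes) and a ``manifest.csv``
    (specimen_id, path, group_label) is produced; the manifest DataFrame
    is returned either way, with in-memory rasters and masks attached as
    the ``surfaces`` attrs dict when ``out_dir`` is None.

    Per-surface seeds are drawn deterministically from the master seed.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    surfaces: dict[str, tuple[ElevationRaster, np.ndarray]] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for cls in classes:
        base = (params_by_class or {}).get(
            cls, SyntheticSurfaceParams(damage_class=cls)
        )
        if base.damage_class != cls:
            base = replace(base, damage_class=cls)
        for i in range(n_per_class):
            sub_seed = int(rng.integers(2**31))
            p = replace(base, seed=sub_seed)
            raster, mask = generate_surface(p)
            sid = f"{cls}_{i:03d}"
            if out is not None:
                path = out / f"{sid}.asc"
                write_ascii_grid(raster, path)
                if write_masks:
                    write_ascii_grid(
                        ElevationRaster(
                            z=mask.astype(float),
                            nodata_mask=np.zeros_like(mask),
                            origin=raster.origin,
                            cell_size=raster.cell_size,
                        ),
                        out / f"{sid}_mask.asc",
                    )
                if write_meshes:
                    from .mesh_io import write_mesh

                    write_mesh(raster_to_mesh(raster), out / f"{sid}.ply")
                rows.append(
                    {"specimen_id": sid, "path": path.name, "group_label": cls}
                )
            else:
                surfaces[sid] = (raster, mask)
                rows.append(
                    {"specimen_id": sid, "path": "", "group_label": cls}
                )
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    else:
        manifest.attrs["surfaces"] = surfaces
    return manifest
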