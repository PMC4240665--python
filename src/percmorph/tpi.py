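"""Topographic position index (TPI) over a micro-DEM.

TPI is each cell's elevation minus the mean elevation of a moving-window
neighbourhood: positive at local peaks, negative in local valleys. On
stone-surface micro-topography it measures rugosity — the pits-and-ridges
texture left by percussion — while being insensitive to broad curvature of
the scanned surface at small window sizes.

Edge cells whose window falls mostly outside the grid (or on nodata) are
masked out rather than computed from a truncated window, so the well-known
edge artefacts of moving-window indices appear as an explicit validity mask
instead of biased values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rasterize import ElevationRaster

__all__ = ["WindowSpec", "TPIRaster", "compute_tpi"]


class WindowExceedsRasterError(ValueError):
    """Window larger than the raster in both dimensions."""


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window neighbourhood specification.

    shape : "square" (Chebyshev radius ``outer_radius``) or "annulus"
        (Euclidean ``inner_radius`` < d <= ``outer_radius``), in cells.
    include_center : whether the focal cell enters its own neighbourhood
        mean (the default excludes it, so TPI is a pure self-vs-surround
        difference).
    """

    shape: str = "square"
    outer_radius: int = 3
    inner_radius: int = 0
    include_center: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("square", "annulus"):
            raise ValueError("shape must be 'square' or 'annulus'")
        if self.outer_radius < 1:
            raise ValueError("outer_radius must be >= 1")
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("require 0 <= inner_radius < outer_radius")

    def kernel(self) -> np.ndarray:
        """Boolean neighbourhood footprint, centred, side 2*outer_radius+1."""
        r = self.outer_radius
        di, dj = np.mgrid[-r : r + 1, -r : r + 1]
        if self.shape == "square":
            k = np.ones_like(di, dtype=bool)
        else:
            d = np.hypot(di, dj)
            k = (d > self.inner_radius) & (d <= r + 1e-9)
        if not self.include_center:
            k[r, r] = False
        return k


@dataclass
class TPIRaster:
    """Per-cell TPI values with a validity mask.

    ``valid_mask`` is True only where the DEM has data *and* the window had
    sufficient coverage; grid geometry mirrors the source DEM.
    """

    tpi: np.ndarray
    valid_mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    window: WindowSpec = field(default_factory=WindowSpec)
    projection_axis: str = "+z"

    @property
    def n_rows(self) -> int:
        return self.tpi.shape[0]

    @property
    def n_cols(self) -> int:
        return self.tpi.shape[1]

    def cell_center(self, row, col):
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - 1 - np.asarray(row) + 0.5) * self.cell_size
        return x, y


def compute_tpi(
    dem: ElevationRaster,
    window: WindowSpec | None = None,
    min_coverage: float = 1.0,
) -> TPIRaster:
    """Compute TPI with the given moving window.

    A cell is valid when it has data and at least ``min_coverage`` of the
    full window footprint consists of unmasked neighbours; other cells get
    ``valid_mask = False`` and a TPI of NaN.
    """
    if window is None:
        window = WindowSpec()
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    data = ~dem.nodata_mask
    if not data.any():
        raise ValueError("DEM has no unmasked cells")
    side = 2 * window.outer_radius + 1
    if side > dem.n_rows and side > dem.n_cols:
        raise WindowExceedsRasterError(
            f"window side {side} exceeds raster {dem.n_rows}x{dem.n_cols}"
        )
    k = window.kernel().astype(float)
    full = k.sum()
    zf = np.where(data, dem.z, 0.0)
    nb_sum = ndimage.convolve(zf, k, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(data.astype(float), k, mode="constant", cval=0.0)
    nb_cnt_int = np.rint(nb_cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpi = dem.z - nb_sum / nb_cnt_int
    valid = data & (nb_cnt_int >= min_coverage * full) & (nb_cnt_int > 0)
    tpi = np.where(valid, tpi, np.nan)
    return TPIRaster(
        tpi=tpi,
        valid_mask=valid,
        origin=dem.origin,
        cell_size=dem.cell_size,
        window=window,
        projection_axis=dem.projection_axis,
    )
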