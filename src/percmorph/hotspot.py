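"""Getis-Ord Gi* hot-spot analysis of the TPI field.

The self-inclusive local statistic Gi* flags cells embedded in spatial
clusters of high (hot) or low (cold) values. For cell *i* with binary
symmetric weights w_ij over the n valid cells, values x, global mean X-bar
and population standard deviation S:

    Gi*(i) = (sum_j w_ij x_j - X-bar W_i) /
             (S * sqrt((n U_i - W_i^2) / (n - 1))),

with W_i = sum_j w_ij and U_i = sum_j w_ij^2 (= W_i for binary weights).
Gi* is reported as a z-score; a two-tailed normal p-value accompanies it.
Cells are classed hot/cold when |z| exceeds the two-tailed critical value
at the chosen alpha (0.001 by default, i.e. z ~ 3.29).

Cells with invalid TPI are excluded from n, X-bar, S and from all
neighbour sums, so edge cells do not bias the global moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, special, stats

from .tpi import TPIRaster

__all__ = [
    "HOT",
    "COLD",
    "NONE",
    "INVALID",
    "SpatialWeights",
    "HotspotRaster",
    "ZeroVarianceError",
    "build_weights",
    "getis_ord_gstar",
    "classify_cells",
    "critical_z",
]

log = logging.getLogger(__name__)

# cell classification codes
HOT = 1
COLD = -1
NONE = 0
INVALID = -9

CLASS_NAMES = {HOT: "hot", COLD: "cold", NONE: "none", INVALID: "invalid"}


class ZeroVarianceError(ValueError):
    """Constant TPI field: Gi* undefined."""


@dataclass(frozen=True)
class SpatialWeights:
    """Binary symmetric spatial weights on the raster lattice.

    The neighbourhood is encoded as a set of (drow, dcol) offsets that
    always includes (0, 0): Gi* is the self-inclusive variant. ``n`` is the
    number of valid cells participating.
    """

    scheme: str
    offsets: np.ndarray  # (k, 2) int array, includes (0, 0)
    n: int
    band_distance: float | None = None
    self_included: bool = True

    def kernel(self) -> np.ndarray:
        """Offsets rendered as a centred boolean footprint."""
        r = int(np.abs(self.offsets).max())
        k = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        k[self.offsets[:, 0] + r, self.offsets[:, 1] + r] = True
        return k

    def neighbor_lists(self, valid_mask: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
        """Explicit neighbour lists (including self) over valid cells —
        for inspection/export; the statistic itself uses the footprint."""
        nr, nc = valid_mask.shape
        out: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for i, j in zip(*np.nonzero(valid_mask)):
            nbrs = []
            for di, dj in self.offsets:
                a, b = i + di, j + dj
                if 0 <= a < nr and 0 <= b < nc and valid_mask[a, b]:
                    nbrs.append((int(a), int(b)))
            out[(int(i), int(j))] = nbrs
        return out


@dataclass
class HotspotRaster:
    """Per-cell Gi* z-scores, p-values and hot/cold classification."""

    gi_z: np.ndarray
    p_two_tailed: np.ndarray
    cls: np.ndarray  # int8 codes: HOT/COLD/NONE/INVALID
    valid_mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    alpha: float
    global_mean: float
    global_sd: float
    projection_axis: str = "+z"

    @property
    def n_rows(self) -> int:
        return self.gi_z.shape[0]

    @property
    def n_cols(self) -> int:
        return self.gi_z.shape[1]


def build_weights(
    tpi: TPIRaster, scheme: str = "queen3x3", band_distance: float | None = None
) -> SpatialWeights:
    """Construct binary weights over the valid cells of a TPI raster.

    scheme "queen3x3": the 8 surrounding cells plus self.
    scheme "distance_band": cells whose centre distance is <= band_distance
    (in cell units) plus self.
    """
    n = int(tpi.valid_mask.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    if scheme == "queen3x3":
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
        band = None
    elif scheme == "distance_band":
        if band_distance is None or band_distance < 1:
            raise ValueError("band_distance must be >= 1 cell")
        r = int(np.floor(band_distance))
        offs = [
            (di, dj)
            for di in range(-r, r + 1)
            for dj in range(-r, r + 1)
            if np.hypot(di, dj) <= band_distance + 1e-9
        ]
        band = float(band_distance)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    return SpatialWeights(
        scheme=scheme,
        offsets=np.array(offs, dtype=int),
        n=n,
        band_distance=band,
    )


def critical_z(alpha: float) -> float:
    """Two-tailed critical z for significance level alpha."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    return float(stats.norm.ppf(1 - alpha / 2))


def getis_ord_gstar(
    tpi: TPIRaster, weights: SpatialWeights, alpha: float = 0.001
) -> HotspotRaster:
    """Evaluate Gi* over all valid cells and classify at ``alpha``.

    Raises :class:`ZeroVarianceError` on a constant TPI field. A cell whose
    variance term vanishes (its window covers all n valid cells) is marked
    invalid with a logged warning.
    """
    valid = tpi.valid_mask
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    x = np.where(valid, tpi.tpi, 0.0)
    xbar = float(x.sum() / n)
    s = float(np.sqrt(np.maximum((x * x)[valid].sum() / n - xbar * xbar, 0.0)))
    if s == 0.0:
        raise ZeroVarianceError("TPI field has zero variance")

    k = weights.kernel().astype(float)
    local_sum = ndimage.convolve(x, k, mode="constant", cval=0.0)
    w_i = np.rint(
        ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
    )
    # binary weights: U_i = sum w^2 = W_i
    var_term = (n * w_i - w_i * w_i) / (n - 1)
    degenerate = valid & (var_term <= 0)
    if degenerate.any():
        log.warning(
            "%d cell(s) with window covering all valid cells marked invalid",
            int(degenerate.sum()),
        )
    ok = valid & (var_term > 0)
    gi_z = np.full(x.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        gi_z[ok] = (local_sum[ok] - xbar * w_i[ok]) / (
            s * np.sqrt(var_term[ok])
        )
    p = np.full(x.shape, np.nan)
    p[ok] = special.erfc(np.abs(gi_z[ok]) / np.sqrt(2.0))
    hs = HotspotRaster(
        gi_z=gi_z,
        p_two_tailed=p,
        cls=np.full(x.shape, INVALID, dtype=np.int8),
        valid_mask=ok,
        origin=tpi.origin,
        cell_size=tpi.cell_size,
        alpha=alpha,
        global_mean=xbar,
        global_sd=s,
        projection_axis=tpi.projection_axis,
    )
    return classify_cells(hs, alpha)


def classify_cells(
    hs: HotspotRaster, alpha: float, fdr: bool = False
) -> HotspotRaster:
    """Fill the hot/cold/none classification at significance level alpha.

    By default each cell is thresholded at its raw two-tailed p (the
    published per-cell p < alpha rule). With ``fdr=True`` the
    Benjamini-Hochberg procedure controls the false discovery rate across
    cells instead — stricter on large rasters, provided for sensitivity
    analysis only.
    """
    z_crit = critical_z(alpha)
    cls = np.full(hs.gi_z.shape, INVALID, dtype=np.int8)
    ok = hs.valid_mask
    cls[ok] = NONE
    if fdr:
        p = hs.p_two_tailed[ok]
        order = np.argsort(p)
        m = p.size
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = p[order] <= thresh
        k = np.nonzero(passed)[0].max() + 1 if passed.any() else 0
        sig = np.zeros(m, dtype=bool)
        sig[order[:k]] = True
        sig_mask = np.zeros(hs.gi_z.shape, dtype=bool)
        sig_mask[ok] = sig
        cls[sig_mask & (hs.gi_z > 0)] = HOT
        cls[sig_mask & (hs.gi_z < 0)] = COLD
    else:
        cls[ok & (hs.gi_z >= z_crit)] = HOT
        cls[ok & (hs.gi_z <= -z_crit)] = COLD
    return replace(hs, cls=cls, alpha=alpha)
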