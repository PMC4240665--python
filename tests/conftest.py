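"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the implementation's code paths: the Gi*
oracle evaluates the formula cell by cell from raw coordinates, the
perimeter oracle counts exposed outer edges via an outside flood fill, and
the Mann-Whitney oracle enumerates rank assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from percmorph.rasterize import ElevationRaster
from percmorph.tpi import TPIRaster, WindowSpec


def make_raster(z, cell_size=1.0, nodata=None, origin=(0.0, 0.0)):
    z = np.asarray(z, dtype=float)
    mask = (
        np.zeros(z.shape, dtype=bool)
        if nodata is None
        else np.asarray(nodata, dtype=bool)
    )
    return ElevationRaster(
        z=z, nodata_mask=mask, origin=origin, cell_size=cell_size
    )


def make_tpi(values, cell_size=1.0, valid=None):
    """Wrap an array directly as a TPIRaster (all cells valid by default),
    so hot-spot statistics can be tested on controlled fields."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return TPIRaster(
        tpi=np.where(valid, values, np.nan),
        valid_mask=np.asarray(valid, dtype=bool),
        origin=(0.0, 0.0),
        cell_size=cell_size,
        window=WindowSpec(),
    )


def gi_star_oracle(values, valid, scheme="queen3x3", band_distance=None):
    """Direct per-cell evaluation of the Gi* formula.

    Neighbour membership is decided from raw cell coordinates (Chebyshev
    distance <= 1 for queen3x3, Euclidean distance <= band for
    distance_band, self always included); sums run over explicit index
    arrays rather than convolutions.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    ii, jj = np.nonzero(valid)
    x = values[ii, jj]
    n = x.size
    xbar = x.mean()
    s = math.sqrt(max((x * x).mean() - xbar * xbar, 0.0))
    out = np.full(values.shape, np.nan)
    for a, b in zip(ii, jj):
        if scheme == "queen3x3":
            member = (np.abs(ii - a) <= 1) & (np.abs(jj - b) <= 1)
        else:
            member = np.hypot(ii - a, jj - b) <= band_distance + 1e-9
        w = member.sum()
        num = x[member].sum() - xbar * w
        den = s * math.sqrt((n * w - w * w) / (n - 1))
        if den > 0:
            out[a, b] = num / den
    return out


def outer_perimeter_oracle(mask, cell_size=1.0):
    """Outer-boundary perimeter of every True region of ``mask`` combined:
    count edges between mask cells and outside-connected background.

    Background connectivity is 4-connected from a padded border, so
    interior holes are excluded — matching the outer-ring-only perimeter
    definition.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    outside = np.zeros_like(padded)
    stack = [(0, 0)]
    outside[0, 0] = True
    nr, nc = padded.shape
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < nr and 0 <= b < nc and not padded[a, b] and not outside[a, b]:
                outside[a, b] = True
                stack.append((a, b))
    edges = 0
    for i, j in zip(*np.nonzero(padded)):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if outside[i + di, j + dj]:
                edges += 1
    return edges * cell_size


def mann_whitney_enum_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of the
    C(n+m, n) equally-likely rank assignments (tie-free data only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(n + m)
    ranks[order] = np.arange(1, n + m + 1)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    u_obs = min(u_obs, n * m - u_obs)
    count = 0
    total = 0
    all_ranks = np.arange(1, n + m + 1)
    for combo in itertools.combinations(range(n + m), n):
        u = all_ranks[list(combo)].sum() - n * (n + 1) / 2
        u = min(u, n * m - u)
        if u <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)
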