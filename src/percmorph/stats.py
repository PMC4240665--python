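"""Nonparametric group discrimination: Mann-Whitney U with Bonferroni.

Group contrasts (experimental vs natural vs archaeological, or synthetic
anthropogenic vs natural) are tested metric-by-metric with two-sided
Mann-Whitney U tests. U is reported as min(U_a, U_b) — the convention under
which small published U values are read. The exact null distribution is
used for small tie-free samples; otherwise the normal approximation with
tie and continuity corrections. Family-wise error across the pairwise
comparisons of a metric is controlled by Bonferroni.

Polygon-level observations are pooled across a group's specimens, which
ignores within-specimen clustering; comparisons carry a caveat string
noting this.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "bonferroni",
    "compare_groups",
    "comparisons_to_dataframe",
]

log = logging.getLogger(__name__)

#: largest per-sample size for which the exact (enumeration) p is used
EXACT_N_MAX = 10

POOLING_CAVEAT = (
    "polygon-level observations pooled across specimens; "
    "within-specimen clustering not modelled"
)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float  # min(U_a, U_b)
    p_raw: float
    p_bonferroni: float
    m_tests: int
    method: str  # "exact" | "normal_approx"
    median_a: float
    median_b: float

    @property
    def direction(self) -> str:
        if self.median_a > self.median_b:
            return f"{self.group_a} > {self.group_b}"
        if self.median_a < self.median_b:
            return f"{self.group_a} < {self.group_b}"
        return f"{self.group_a} ~ {self.group_b}"


def mann_whitney_u(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p, method) with U = min(U_x, U_y) computed via midranks.
    The exact p (full enumeration of rank assignments) is used when both
    samples have <= 10 observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one observation")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        log.warning("all observations identical: p = 1 by convention")
        return n * m / 2.0, 1.0, "normal_approx"
    ties = np.unique(pooled).size < pooled.size
    exact = n <= EXACT_N_MAX and m <= EXACT_N_MAX and not ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_x = float(res.statistic)
    u_min = min(u_x, n * m - u_x)
    return u_min, float(res.pvalue), "exact" if exact else "normal_approx"


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    pairs: list[tuple[str, str]] | None = None,
    group_col: str = "group_label",
) -> list[GroupComparison]:
    """Pairwise Mann-Whitney comparisons of one metric across groups.

    ``table`` is tidy: one observation per row, with a group column and a
    ``metric`` column (NaNs dropped). ``pairs`` defaults to all unordered
    group pairs in sorted label order; the Bonferroni family size m is the
    number of pairs actually tested and is recorded on every result.
    Pairs with an empty group are skipped with a logged reason.
    """
    if metric not in table.columns:
        raise ValueError(f"metric column {metric!r} not in table")
    sub = table[[group_col, metric]].dropna()
    by_group = {g: v[metric].to_numpy() for g, v in sub.groupby(group_col)}
    if pairs is None:
        pairs = list(itertools.combinations(sorted(by_group), 2))
    usable = []
    for a, b in pairs:
        if len(by_group.get(a, ())) < 1 or len(by_group.get(b, ())) < 1:
            log.warning("skipping %s vs %s for %s: empty group", a, b, metric)
            continue
        usable.append((a, b))
    m = len(usable)
    out = []
    for a, b in usable:
        xa, xb = by_group[a], by_group[b]
        u, p, method = mann_whitney_u(xa, xb)
        out.append(
            GroupComparison(
                metric=metric,
                group_a=a,
                group_b=b,
                n_a=len(xa),
                n_b=len(xb),
                U=u,
                p_raw=p,
                p_bonferroni=bonferroni(p, m),
                m_tests=m,
                method=method,
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
            )
        )
    return out


def comparisons_to_dataframe(comps: list[GroupComparison]) -> pd.DataFrame:
    rows = [
        {
            "metric": c.metric,
            "group_a": c.group_a,
            "group_b": c.group_b,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "U": c.U,
            "p_raw": c.p_raw,
            "p_bonferroni": c.p_bonferroni,
            "m_tests": c.m_tests,
            "method": c.method,
            "median_a": c.median_a,
            "median_b": c.median_b,
            "direction": c.direction,
        }
        for c in comps
    ]
    return pd.DataFrame(rows)
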