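"""Wealth-inequality (Gini) series from house floor areas.

House floor area is the wealth proxy: the Gini coefficient of the
floor-area distribution within a period measures how unequally built
space — and by extension household wealth — was distributed. The
uncorrected population Gini

    G = sum_ij |x_i - x_j| / (2 n^2 mu)

is the default (scale-invariant, 0 = perfect equality); the small-sample
correction n/(n-1) is available behind a flag. Uncertainty comes from a
percentile bootstrap over houses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .periods import PeriodTable

GINI_SERIES_COLUMNS = ["period", "n", "gini", "ci_low", "ci_high", "corrected"]


@dataclass(frozen=True)
class GiniEstimate:
    period: str | None
    n: int
    gini: float
    ci_low: float
    ci_high: float
    corrected: bool
    reason: str | None = None  # set when the estimate is undefined


def gini(values, corrected: bool = False) -> float:
    """Gini coefficient of a sequence of nonnegative values.

    Computed from the sorted values in O(n log n):
    G = 2*sum(i*x_(i))/(n*sum(x)) - (n+1)/n, identical to the pairwise
    mean-absolute-difference form. ``corrected=True`` applies the
    small-sample factor n/(n-1).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"gini requires at least 2 values, got {n}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise DomainError("gini requires finite nonnegative values")
    total = x.sum()
    if total == 0:
        raise DomainError("gini is undefined when all values are zero")
    i = np.arange(1, n + 1)
    g = 2.0 * np.dot(i, x) / (n * total) - (n + 1) / n
    if corrected:
        g *= n / (n - 1)
    return float(g)


def gini_bootstrap(
    values,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    corrected: bool = False,
    period: str | None = None,
) -> GiniEstimate:
    """Point estimate plus percentile bootstrap interval at level 1 - alpha.

    B resamples with replacement; deterministic under ``seed``. The interval
    is clipped to [0, 1].
    """
    x = np.asarray(values, dtype=float)
    point = gini(x, corrected=corrected)
    if B < 100:
        raise DomainError(f"bootstrap requires B >= 100, got {B}")
    rng = np.random.default_rng(seed)
    n = x.size
    samples = np.sort(x[rng.integers(0, n, size=(B, n))], axis=1)
    totals = samples.sum(axis=1)
    i = np.arange(1, n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = 2.0 * (samples @ i) / (n * totals) - (n + 1) / n
    reps[totals == 0] = 0.0  # an all-zero resample carries no inequality
    if corrected:
        reps *= n / (n - 1)
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    lo = min(float(np.clip(lo, 0.0, 1.0)), point)
    hi = max(float(np.clip(hi, 0.0, 1.0)), point)
    return GiniEstimate(period, int(n), point, lo, hi, corrected)


def gini_by_period(
    houses: pd.DataFrame,
    periods: PeriodTable,
    corrected: bool = False,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_n: int = 5,
) -> list[GiniEstimate]:
    """One Gini estimate per period of the grid, in period order.

    Houses are the unit of observation. Periods with fewer than ``min_n``
    houses are reported with NaN Gini and a recorded reason rather than
    dropped, so downstream joins keep one row per period. Set ``B=0`` to
    skip bootstrap intervals (point estimates only).

    Raises KeyError if a house references a period absent from the grid.
    """
    known = set(periods.names)
    bad = set(houses["period"]) - known
    if bad:
        raise KeyError(f"houses reference unknown periods: {sorted(bad)}")
    if np.any(houses["area_m2"].to_numpy(dtype=float) <= 0):
        raise DomainError("house areas must be strictly positive")
    groups = {name: g["area_m2"].to_numpy(dtype=float) for name, g in houses.groupby("period")}
    substreams = np.random.SeedSequence(seed).spawn(len(periods))
    out: list[GiniEstimate] = []
    for pname, ss in zip(periods.names, substreams):
        x = groups.get(pname, np.empty(0))
        if x.size < max(min_n, 2):
            out.append(
                GiniEstimate(
                    pname, int(x.size), math.nan, math.nan, math.nan, corrected,
                    reason=f"n={x.size} below min_n={min_n}",
                )
            )
            continue
        if B == 0:
            point = gini(x, corrected=corrected)
            out.append(GiniEstimate(pname, int(x.size), point, math.nan, math.nan, corrected))
        else:
            out.append(
                gini_bootstrap(x, B=B, alpha=alpha, seed=ss, corrected=corrected, period=pname)
            )
    return out


def gini_series_frame(estimates: list[GiniEstimate]) -> pd.DataFrame:
    """Tabular form of a Gini series (the gini-series CSV schema)."""
    return pd.DataFrame(
        {
            "period": [e.period for e in estimates],
            "n": [e.n for e in estimates],
            "gini": [e.gini for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "corrected": [e.corrected for e in estimates],
        }
    )
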