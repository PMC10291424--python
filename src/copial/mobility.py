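"""Mobility statistics: midpoint growth rates, churn, settlement persistence.

*Churn* is a migration-scale mobility proxy: for each archaeological period
it counts how many subregions grew or shrank by at least 0.7 %/yr
(annualized, midpoint to midpoint) — growth of that size more plausibly
reflects people moving in or out than natural increase. With six subregions
the index is bounded between 0 and 6.

*Persistence* is the mean occupation-span length of settlements founded in
each period; long spans mean reduced residential mobility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataCoverageError, DomainError, InsufficientDataError
from .periods import Period, PeriodTable, default_period_grid

__all__ = [
    "Period",
    "PeriodTable",
    "default_period_grid",
    "ChurnResult",
    "annualized_growth",
    "churn",
    "churn_frame",
    "persistence_by_period",
]

CHURN_THRESHOLD_DEFAULT = 0.7  # percent per year


@dataclass(frozen=True)
class ChurnResult:
    """Churn for one period: per-subregion rates plus the exceedance count.

    ``rates`` maps subregion id to annualized %/yr growth from the previous
    period midpoint, or NaN where a zero-population endpoint makes the rate
    undefined (a colonization or abandonment event, listed in ``events``).
    Undefined rates are excluded from the churn count.
    """

    period: str
    rates: dict = field(default_factory=dict)
    churn: int = 0
    threshold: float = CHURN_THRESHOLD_DEFAULT
    events: dict = field(default_factory=dict)  # subregion -> "colonization"/"abandonment"


def annualized_growth(p1: float, p2: float, dt: float) -> float:
    """Annualized percent-per-year growth taking p1 to p2 over dt years.

    Geometric (compound) annualization: r = 100 * ((p2/p1)**(1/dt) - 1).
    Returns NaN when either endpoint is zero — a rate is not measurable
    across a colonization or abandonment.
    """
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    if p1 < 0 or p2 < 0:
        raise DomainError("populations must be nonnegative")
    if p1 == 0 or p2 == 0:
        return math.nan
    return 100.0 * ((p2 / p1) ** (1.0 / dt) - 1.0)


def churn(
    pops: pd.DataFrame,
    periods: PeriodTable,
    threshold: float = CHURN_THRESHOLD_DEFAULT,
) -> list[ChurnResult]:
    """Churn for every period after the first.

    ``pops`` has columns subregion_id, period, population, one row per
    (subregion, period). The rate for subregion s in period k is the
    annualized growth of s from midpoint(k-1) to midpoint(k); churn counts
    subregions with \\|rate\\| >= threshold (boundary included: "equal or
    exceed").

    Raises
    ------
    DataCoverageError
        Listing every missing (subregion, period) cell.
    InsufficientDataError
        If the grid has fewer than two periods.
    """
    if len(periods) < 2:
        raise InsufficientDataError("churn requires at least two periods")
    subregions = sorted(set(pops["subregion_id"]))
    table = pops.set_index(["subregion_id", "period"])["population"]
    if table.index.has_duplicates:
        raise DataCoverageError("duplicate (subregion, period) rows in population table")
    gaps = [
        (s, p.name)
        for s in subregions
        for p in periods
        if (s, p.name) not in table.index
    ]
    if gaps:
        raise DataCoverageError(f"missing subregion-period cells: {gaps}")

    out: list[ChurnResult] = []
    for prev, cur in zip(periods, list(periods)[1:]):
        dt = cur.midpoint_year - prev.midpoint_year
        rates: dict = {}
        events: dict = {}
        for s in subregions:
            p1 = float(table[(s, prev.name)])
            p2 = float(table[(s, cur.name)])
            r = annualized_growth(p1, p2, dt)
            rates[s] = r
            if math.isnan(r):
                if p1 == 0 and p2 > 0:
                    events[s] = "colonization"
                elif p1 > 0 and p2 == 0:
                    events[s] = "abandonment"
                else:
                    events[s] = "unoccupied"
        count = sum(
            1 for r in rates.values() if not math.isnan(r) and abs(r) >= threshold
        )
        out.append(ChurnResult(cur.name, rates, count, threshold, events))
    return out


def churn_frame(results: list[ChurnResult]) -> pd.DataFrame:
    """Tabular churn output: one row per period, one rate column per subregion."""
    subregions = sorted({s for r in results for s in r.rates})
    rows = []
    for r in results:
        row = {"period": r.period}
        for s in subregions:
            row[f"rate_{s}"] = r.rates.get(s, math.nan)
        row["churn"] = r.churn
        row["threshold"] = r.threshold
        rows.append(row)
    return pd.DataFrame(rows)


def persistence_by_period(
    ledger: pd.DataFrame,
    periods: PeriodTable,
    by_size_class: bool = False,
    houses: pd.DataFrame | None = None,
    village_min_houses: int = 3,
) -> pd.DataFrame:
    """Mean occupation-span length per period (persistence).

    A span is assigned to the period containing its start year (spans
    starting outside the grid are ignored); its length is
    end_year - start_year + 1 (closed intervals, so a single-year span has
    length 1). With ``by_size_class=True`` and a house table, settlements
    with at least ``village_min_houses`` houses (over all periods) are
    classed as villages, the rest as hamlets, and means are reported per
    (period, size_class).

    Returns a frame with columns period [, size_class], mean_span_yr, n —
    one row per period (times size class), NaN mean where no span starts.
    """
    if len(ledger) == 0:
        raise InsufficientDataError("occupancy ledger is empty")
    spans = ledger.copy()
    spans["span_yr"] = spans["end_year"] - spans["start_year"] + 1
    if (spans["span_yr"] <= 0).any():
        raise DomainError("occupation spans must satisfy end_year >= start_year")
    spans["period"] = [periods.period_of(int(y)) for y in spans["start_year"]]
    spans = spans.dropna(subset=["period"])

    if by_size_class:
        if houses is None:
            raise DomainError("by_size_class requires a house table")
        counts = houses.groupby("settlement_id").size()
        spans["size_class"] = [
            "village" if counts.get(s, 0) >= village_min_houses else "hamlet"
            for s in spans["settlement_id"]
        ]
        keys = ["period", "size_class"]
        index = pd.MultiIndex.from_product(
            [periods.names, ["hamlet", "village"]], names=keys
        )
    else:
        keys = ["period"]
        index = pd.Index(periods.names, name="period")

    agg = spans.groupby(keys)["span_yr"].agg(mean_span_yr="mean", n="size")
    agg = agg.reindex(index)
    agg["n"] = agg["n"].fillna(0).astype(int)
    return agg.reset_index()
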