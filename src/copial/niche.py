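"""Dry-farming niche classification and occupancy-aware niche statistics.

A landscape cell-year is in the maize direct-precipitation farming niche
(MFN) when its water-year precipitation exceeds 30 cm *and* its Fahrenheit
growing degree days (FGDD) exceed 1800. Crossing occupancy records with the
niche classification yields an annual series of mobility-relevant measures,
chief among them *room to walk*:

    room_to_walk(t) = (occupied cells in MFN / occupied cells)
                      - (cells in MFN / all cells)

High values mean plenty of unoccupied farmable land; the second term strips
most climate-driven variability out of the first, leaving a primarily
demographic signal. Occupancy in year t counts any settlement span that
intersects the present year or a short trailing lookback window (default
3 years), and the annual series is conventionally smoothed with a one-sided
trailing moving average (default 11 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataCoverageError, DomainError

#: Column order of the niche-series CSV.
NICHE_SERIES_COLUMNS = [
    "year",
    "n_cells_total",
    "n_cells_in_niche",
    "n_occupied",
    "n_occupied_in_niche",
    "niche_frac",
    "occupied_in_niche_frac",
    "room_to_walk",
    "room_to_walk_smoothed",
    "unoccupied_niche_frac",
]


@dataclass(frozen=True)
class NicheParams:
    """Thresholds and window lengths for niche classification.

    Parameters
    ----------
    precip_threshold_cm, fgdd_threshold
        Water-year precipitation (cm) and Fahrenheit growing degree days a
        cell must *exceed* to be in the niche.
    occupancy_lookback_yr
        A cell counts as occupied in year t if a span intersects
        [t - lookback, t].
    smoothing_window_yr
        Length of the trailing moving-average window.
    inclusive_thresholds
        If True, read "exceeding" as >= instead of the default strict >.
    window_includes_current
        If True (default) the smoothing window is [t-w+1, t]; if False it is
        the w strictly prior years [t-w, t-1].
    """

    precip_threshold_cm: float = 30.0
    fgdd_threshold: float = 1800.0
    occupancy_lookback_yr: int = 3
    smoothing_window_yr: int = 11
    inclusive_thresholds: bool = False
    window_includes_current: bool = True

    def __post_init__(self) -> None:
        if self.precip_threshold_cm <= 0:
            raise ConfigurationError("precip_threshold_cm must be strictly positive")
        if self.fgdd_threshold <= 0:
            raise ConfigurationError("fgdd_threshold must be strictly positive")
        if self.occupancy_lookback_yr < 0:
            raise ConfigurationError("occupancy_lookback_yr must be >= 0")
        if self.smoothing_window_yr < 1:
            raise ConfigurationError("smoothing_window_yr must be >= 1")


def in_niche(precip_cm, fgdd, params: NicheParams = NicheParams()):
    """Classify one or many (precipitation, FGDD) pairs as in/out of the niche.

    Accepts scalars or numpy arrays; returns a bool or bool array. Both
    thresholds must be exceeded (a conjunction): generous rain with a short
    growing season fails, and vice versa.
    """
    precip = np.asarray(precip_cm, dtype=float)
    heat = np.asarray(fgdd, dtype=float)
    if not (np.all(np.isfinite(precip)) and np.all(np.isfinite(heat))):
        raise DomainError("in_niche requires finite precipitation and FGDD values")
    if params.inclusive_thresholds:
        result = (precip >= params.precip_threshold_cm) & (heat >= params.fgdd_threshold)
    else:
        result = (precip > params.precip_threshold_cm) & (heat > params.fgdd_threshold)
    if np.isscalar(precip_cm) and np.isscalar(fgdd):
        return bool(result)
    return result


def occupied_mask(ledger: pd.DataFrame, year: int, params: NicheParams = NicheParams()) -> set:
    """Cells occupied in ``year``: some span intersects [year - lookback, year].

    ``ledger`` has columns cell_id, settlement_id, start_year, end_year
    (closed intervals). An empty ledger yields an empty set.
    """
    if len(ledger) == 0:
        return set()
    lo = year - params.occupancy_lookback_yr
    hit = (ledger["start_year"] <= year) & (ledger["end_year"] >= lo)
    return set(ledger.loc[hit, "cell_id"])


def niche_series(
    climate: pd.DataFrame,
    ledger: pd.DataFrame,
    params: NicheParams = NicheParams(),
) -> pd.DataFrame:
    """Annual niche and occupancy statistics over the climate table's years.

    For every year present in ``climate`` the result reports cell counts,
    the niche fraction, the occupied-in-niche fraction, room to walk (NaN in
    years with no occupied cells: 0/0 is not evidence of zero), its trailing
    smoothed version, and the unoccupied-niche fraction
    (n_in_niche - n_occupied_in_niche) / n_cells_total.

    Raises
    ------
    DataCoverageError
        If an occupied cell-year has no climate record: occupancy outside
        climate coverage would silently corrupt the denominators.
    """
    if len(climate) == 0:
        raise DataCoverageError("climate table is empty")
    clim = climate.copy()
    clim["in_niche"] = in_niche(
        clim["precip_cm"].to_numpy(), clim["fgdd"].to_numpy(), params
    )

    per_year = (
        clim.groupby("year", sort=True)
        .agg(n_cells_total=("cell_id", "size"), n_cells_in_niche=("in_niche", "sum"))
        .reset_index()
    )

    niche_cells = {
        yr: set(g.loc[g["in_niche"], "cell_id"]) for yr, g in clim.groupby("year")
    }
    climate_cells = {yr: set(g["cell_id"]) for yr, g in clim.groupby("year")}

    rows = []
    for _, rec in per_year.iterrows():
        yr = int(rec["year"])
        occ = occupied_mask(ledger, yr, params)
        missing = occ - climate_cells[yr]
        if missing:
            raise DataCoverageError(
                f"year {yr}: occupied cells without climate records: "
                f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
            )
        n_total = int(rec["n_cells_total"])
        n_niche = int(rec["n_cells_in_niche"])
        n_occ = len(occ)
        n_occ_niche = len(occ & niche_cells[yr])
        niche_frac = n_niche / n_total
        occ_in_niche_frac = n_occ_niche / n_occ if n_occ > 0 else math.nan
        rtw = occ_in_niche_frac - niche_frac if n_occ > 0 else math.nan
        rows.append(
            {
                "year": yr,
                "n_cells_total": n_total,
                "n_cells_in_niche": n_niche,
                "n_occupied": n_occ,
                "n_occupied_in_niche": n_occ_niche,
                "niche_frac": niche_frac,
                "occupied_in_niche_frac": occ_in_niche_frac,
                "room_to_walk": rtw,
                "unoccupied_niche_frac": (n_niche - n_occ_niche) / n_total,
            }
        )
    out = pd.DataFrame(rows)
    smoothed = smooth_trailing(
        out.set_index("year")["room_to_walk"],
        params.smoothing_window_yr,
        include_current=params.window_includes_current,
    )
    out["room_to_walk_smoothed"] = smoothed.to_numpy()
    return out[NICHE_SERIES_COLUMNS]


def smooth_trailing(
    series: pd.Series, window: int, include_current: bool = True
) -> pd.Series:
    """One-sided (trailing) moving average over a year-indexed series.

    The value at year t is the mean of the defined values in [t-window+1, t]
    (or [t-window, t-1] with ``include_current=False``). The window is
    truncated at the series start; NaN inputs are skipped; the output is NaN
    where no defined value falls in the window. Years absent from the index
    are treated as undefined, not as zeros.
    """
    if window < 1:
        raise ConfigurationError("smoothing window must be >= 1")
    if len(series) == 0:
        return series.copy()
    idx = pd.RangeIndex(int(series.index.min()), int(series.index.max()) + 1)
    dense = series.reindex(idx).astype(float)
    if not include_current:
        dense = dense.shift(1)
    smoothed = dense.rolling(window, min_periods=1).mean()
    return smoothed.reindex(series.index)
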