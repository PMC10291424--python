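"""CSV schemas shared by every stage.

All files are comma-separated, UTF-8, with a header row; years are
integers; missing values are empty fields. Floats are written with
%.10g so identical computations produce byte-identical files.

    cells.csv:        cell_id, year, precip_cm, fgdd
    occupations.csv:  cell_id, settlement_id, start_year, end_year
    houses.csv:       house_id, settlement_id, period, area_m2
    populations.csv:  subregion_id, period, population
    periods.csv:      name, start_year, end_year
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DomainError
from .periods import Period, PeriodTable

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, path, ["cell_id", "year", "precip_cm", "fgdd"])
    if df.duplicated(["cell_id", "year"]).any():
        raise DomainError(f"{path}: duplicate (cell_id, year) records")
    if (df["precip_cm"] < 0).any() or (df["fgdd"] < 0).any():
        raise DomainError(f"{path}: precipitation and FGDD must be nonnegative")
    return df


def read_occupations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, path, ["cell_id", "settlement_id", "start_year", "end_year"])
    if (df["end_year"] < df["start_year"]).any():
        raise DomainError(f"{path}: occupation spans need end_year >= start_year")
    return df


def read_houses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, path, ["house_id", "settlement_id", "period", "area_m2"])
    if (df["area_m2"] <= 0).any():
        raise DomainError(f"{path}: house areas must be strictly positive")
    return df


def read_populations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, path, ["subregion_id", "period", "population"])
    if (df["population"] < 0).any():
        raise DomainError(f"{path}: populations must be nonnegative")
    return df


def read_periods(path: str | Path) -> PeriodTable:
    df = pd.read_csv(path)
    _require(df, path, ["name", "start_year", "end_year"])
    return PeriodTable(
        tuple(
            Period(str(r["name"]), int(r["start_year"]), int(r["end_year"]))
            for _, r in df.iterrows()
        )
    )


def write_periods(periods: PeriodTable, path: str | Path) -> None:
    write_csv(periods.to_frame()[["name", "start_year", "end_year"]], path)


def _require(df: pd.DataFrame, path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
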