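"""Archaeological period grids.

A period grid is the join key for every period-level statistic in the
pipeline: Gini series, churn, persistence and the period-aggregated niche
statistics are all indexed by period name. Periods are closed calendar-year
intervals that must be chronologically ordered and non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class Period:
    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ConfigurationError(
                f"period {self.name!r}: end_year ({self.end_year}) must exceed "
                f"start_year ({self.start_year})"
            )

    @property
    def midpoint_year(self) -> float:
        return (self.start_year + self.end_year) / 2.0

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass(frozen=True)
class PeriodTable:
    """Ordered, non-overlapping sequence of named periods."""

    periods: tuple[Period, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.periods, self.periods[1:]):
            if cur.start_year <= prev.end_year:
                raise ConfigurationError(
                    f"periods {prev.name!r} and {cur.name!r} overlap or are out of order"
                )
        names = [p.name for p in self.periods]
        if len(set(names)) != len(names):
            raise ConfigurationError("period names must be unique")

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self):
        return iter(self.periods)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.periods]

    def __getitem__(self, name: str) -> Period:
        for p in self.periods:
            if p.name == name:
                return p
        raise KeyError(name)

    def period_of(self, year: int) -> str | None:
        """Name of the period containing ``year``, or None if between/outside periods."""
        for p in self.periods:
            if p.contains(year):
                return p.name
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "start_year": [p.start_year for p in self.periods],
                "end_year": [p.end_year for p in self.periods],
                "midpoint_year": [p.midpoint_year for p in self.periods],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeriodTable":
        return cls(
            tuple(
                Period(str(r["name"]), int(r["start_year"]), int(r["end_year"]))
                for _, r in df.iterrows()
            )
        )


def default_period_grid(start: int = 600, end: int = 1299, n_periods: int = 14) -> PeriodTable:
    """Fourteen contiguous 50-year periods spanning AD 600-1300.

    This mirrors the kind of regional chronology used for the upland US
    Southwest; exact boundaries are data, not doctrine, and callers may
    supply any grid.
    """
    if n_periods < 1:
        raise ConfigurationError("n_periods must be >= 1")
    edges = [start + round(i * (end + 1 - start) / n_periods) for i in range(n_periods + 1)]
    periods = tuple(
        Period(f"P{i + 1:02d}", edges[i], edges[i + 1] - 1) for i in range(n_periods)
    )
    return PeriodTable(periods)
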