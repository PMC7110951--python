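"""Year-indexed series containers for census, climate and warden data.

All containers are thin, validated wrappers around numpy arrays with a
strictly increasing integer year axis.  Missing years are absent rows,
never zeros: a zero census count means extinction, not a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PopulationSeries", "ClimateSeries", "WardenSeries"]


def _as_year_axis(years) -> np.ndarray:
    years = np.asarray(years, dtype=np.int64)
    if years.ndim != 1:
        raise ValueError("years must be one-dimensional")
    if years.size > 1 and not np.all(np.diff(years) > 0):
        raise ValueError("years must be strictly increasing (duplicates or disorder found)")
    return years


@dataclass(frozen=True)
class PopulationSeries:
    """Annual animal census counts, possibly with gaps.

    Parameters
    ----------
    year : array-like of int
        Calendar years, strictly increasing; missing years are simply
        absent rows.
    count : array-like of float
        Animals counted in each year; non-negative.  Counts are stored as
        floats because simulated trajectories are continuous.
    season : str, optional
        ``"spring"`` or ``"autumn"``; a label only, it does not change
        any computation.
    """

    year: np.ndarray
    count: np.ndarray
    season: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "year", _as_year_axis(self.year))
        count = np.asarray(self.count, dtype=float)
        if count.shape != self.year.shape:
            raise ValueError("year and count must have the same length")
        if np.any(count < 0):
            bad = self.year[count < 0][0]
            raise ValueError(f"negative count in year {bad}")
        if self.season is not None and self.season not in ("spring", "autumn"):
            raise ValueError(f"season must be 'spring' or 'autumn', got {self.season!r}")
        object.__setattr__(self, "count", count)

    def __len__(self) -> int:
        return self.year.size

    def at(self, year: int) -> float:
        idx = np.searchsorted(self.year, year)
        if idx >= self.year.size or self.year[idx] != year:
            raise KeyError(f"no census count for year {year}")
        return float(self.count[idx])

    def window(self, first: int, last: int) -> "PopulationSeries":
        """Rows with first <= year <= last."""
        m = (self.year >= first) & (self.year <= last)
        return PopulationSeries(self.year[m], self.count[m], self.season)

    def drop_years(self, years) -> "PopulationSeries":
        m = ~np.isin(self.year, np.asarray(list(years), dtype=np.int64))
        return PopulationSeries(self.year[m], self.count[m], self.season)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.year, "count": self.count})
        if self.season is not None:
            df["season"] = self.season
        return df


@dataclass(frozen=True)
class ClimateSeries:
    """Total winter (November--April) precipitation, in millimetres.

    The year is the calendar year the winter *ends* in, so the winter of
    1935--1936 is attributed to 1936.  Precipitation is the proxy used for
    snow depth at high elevation.
    """

    year: np.ndarray
    precip: np.ndarray
    #: number of stations contributing each value (set by station averaging)
    n_stations: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "year", _as_year_axis(self.year))
        precip = np.asarray(self.precip, dtype=float)
        if precip.shape != self.year.shape:
            raise ValueError("year and precip must have the same length")
        if np.any(precip < 0):
            bad = self.year[precip < 0][0]
            raise ValueError(f"negative precipitation in year {bad}")
        object.__setattr__(self, "precip", precip)
        if self.n_stations is not None:
            ns = np.asarray(self.n_stations, dtype=np.int64)
            if ns.shape != self.year.shape:
                raise ValueError("n_stations must match the year axis")
            object.__setattr__(self, "n_stations", ns)

    def __len__(self) -> int:
        return self.year.size

    def at(self, year: int) -> float:
        idx = np.searchsorted(self.year, year)
        if idx >= self.year.size or self.year[idx] != year:
            raise KeyError(f"no precipitation for winter ending {year}")
        return float(self.precip[idx])

    def covers(self, years) -> np.ndarray:
        """Boolean mask: which requested years have a precipitation value."""
        return np.isin(np.asarray(years, dtype=np.int64), self.year)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.year, "winter_precip_mm": self.precip})
        if self.n_stations is not None:
            df["n_stations"] = self.n_stations
        return df


@dataclass(frozen=True)
class WardenSeries:
    """Annual park-warden headcount (surveillance effort)."""

    year: np.ndarray
    wardens: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "year", _as_year_axis(self.year))
        w = np.asarray(self.wardens, dtype=float)
        if w.shape != self.year.shape:
            raise ValueError("year and wardens must have the same length")
        if np.any(w < 0):
            raise ValueError("warden counts must be non-negative")
        object.__setattr__(self, "wardens", w)

    def __len__(self) -> int:
        return self.year.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.year, "wardens": self.wardens})
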