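"""Scripted experiments: windowed fit-forecast-validate runs, proxy
correlation, station averaging, and descriptive lag analyses.

``run_windowed`` is the workhorse protocol: fit the model on the census
up to a cutoff year, launch a stochastic ensemble from the last count of
the fit window, and validate every later observation against the
ensemble band.  Repeating it with different cutoffs (to 1932, to 1934,
...) reproduces the question "up to when do density and climate alone
explain the record?".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    EnsembleForecast,
    FittedModel,
    ValidationReport,
    fit_model,
    simulate_ensemble,
    validate_out_of_sample,
)
from .series import ClimateSeries, PopulationSeries

__all__ = [
    "WindowedExperiment",
    "ProxyReport",
    "run_windowed",
    "proxy_correlation",
    "station_average",
    "lagged_correlation",
    "seasonal_consistency",
]


@dataclass(frozen=True)
class WindowedExperiment:
    variant: str
    fit_window: tuple[int, int]
    forecast_window: tuple[int, int] | None
    n_real: int
    seed: int
    model: FittedModel
    forecast: EnsembleForecast
    report: ValidationReport


@dataclass(frozen=True)
class ProxyReport:
    """Squared Pearson correlation between two annual series over a year
    window -- how well one (e.g. a three-station precipitation average)
    proxies the other (e.g. snow depth at altitude)."""

    window: tuple[int, int]
    r_squared: float
    n_pairs: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_pairs < 3:
            raise ValueError("at least 3 overlapping years required")


def run_windowed(
    pop: PopulationSeries,
    clim: ClimateSeries,
    variant: str,
    fit_end_year: int,
    n_real: int = 1000,
    seed: int = 0,
    band_level: float = 0.90,
) -> WindowedExperiment:
    """Fit on the census up to ``fit_end_year``, forecast from the last
    count of the fit window, validate against all later observations.

    The forecast runs to the last year with both a census and a climate
    value.  When ``fit_end_year`` is the end of the series the forecast
    is empty and the report validates no years (coverage NaN) -- a
    graceful degenerate case, not an error.
    """
    fit_window = (int(pop.year.min()), int(fit_end_year))
    model = fit_model(pop, clim, variant, fit_window)
    in_fit = pop.year[pop.year <= fit_end_year]
    launch_year = int(in_fit.max())
    end_year = min(int(pop.year.max()), int(clim.year.max()))
    if end_year <= launch_year:
        forecast = simulate_ensemble(
            model, pop.at(launch_year), launch_year, clim, n_real=n_real,
            seed=seed, band_level=band_level, end_year=launch_year,
        )
        return WindowedExperiment(
            variant=variant, fit_window=fit_window, forecast_window=None,
            n_real=n_real, seed=seed, model=model, forecast=forecast,
            report=ValidationReport.empty(),
        )
    forecast = simulate_ensemble(
        model, pop.at(launch_year), launch_year, clim, n_real=n_real,
        seed=seed, band_level=band_level, end_year=end_year,
    )
    report = validate_out_of_sample(forecast, pop)
    return WindowedExperiment(
        variant=variant, fit_window=fit_window,
        forecast_window=(launch_year + 1, end_year), n_real=n_real,
        seed=seed, model=model, forecast=forecast, report=report,
    )


def _paired(a_years, a_vals, b_years, b_vals, window=None):
    sa = pd.Series(a_vals, index=a_years)
    sb = pd.Series(b_vals, index=b_years)
    df = pd.concat([sa, sb], axis=1, join="inner", keys=["a", "b"])
    if window is not None:
        df = df.loc[(df.index >= window[0]) & (df.index <= window[1])]
    return df


def proxy_correlation(
    series_a: ClimateSeries,
    series_b: ClimateSeries,
    window: tuple[int, int] | None = None,
) -> ProxyReport:
    """R-squared of the year-paired values of two climate-like series.

    Symmetric in its arguments and invariant to affine rescaling of
    either series (it is a squared Pearson correlation).
    """
    df = _paired(series_a.year, series_a.precip, series_b.year, series_b.precip, window)
    if len(df) < 3:
        raise ValueError(f"only {len(df)} overlapping years; at least 3 required")
    r = stats.pearsonr(df["a"], df["b"]).statistic
    win = window if window is not None else (int(df.index.min()), int(df.index.max()))
    return ProxyReport(window=win, r_squared=min(float(r) ** 2, 1.0), n_pairs=len(df))


def station_average(stations: list[ClimateSeries]) -> ClimateSeries:
    """Per-year arithmetic mean over the stations reporting that year.

    The output year axis is the union of the inputs; the number of
    contributing stations is recorded per year.  Permutation-invariant in
    station order.
    """
    if not stations:
        raise ValueError("at least one station series required")
    frames = [pd.Series(s.precip, index=s.year) for s in stations]
    df = pd.concat(frames, axis=1, join="outer")
    df = df.sort_index()
    return ClimateSeries(
        df.index.to_numpy(dtype=np.int64),
        df.mean(axis=1, skipna=True).to_numpy(),
        n_stations=df.notna().sum(axis=1).to_numpy(),
    )


def lagged_correlation(
    driver,
    response: PopulationSeries,
    lag: int = 1,
    use_changes: bool = True,
    method: str = "pearson",
) -> float:
    """Correlation between driver changes and later population changes.

    By default correlates year-over-year *changes*: the change in the
    driver (e.g. warden headcount) in year ``t - lag`` against the change
    in the population in year ``t``.  ``use_changes=False`` correlates
    levels instead; ``method`` may be ``"pearson"`` or ``"spearman"``.
    ``driver`` is any year-indexed series object with a ``year`` array
    and one value column (``wardens``, ``precip`` or ``count``).
    """
    d_years = np.asarray(driver.year)
    for attr in ("wardens", "precip", "count"):
        if hasattr(driver, attr):
            d_vals = np.asarray(getattr(driver, attr), dtype=float)
            break
    else:
        raise TypeError("driver must carry a wardens/precip/count value column")
    r_years, r_vals = response.year, response.count
    if use_changes:
        # first differences require consecutive years on both sides
        def diffs(years, vals):
            keep = np.diff(years) == 1
            return years[1:][keep], np.diff(vals)[keep]

        d_years, d_vals = diffs(d_years, d_vals)
        r_years, r_vals = diffs(r_years, r_vals)
    df = _paired(d_years + lag, d_vals, r_years, r_vals)
    if len(df) < 3:
        raise ValueError(f"only {len(df)} overlapping pairs at lag {lag}; need 3")
    if method == "pearson":
        return float(stats.pearsonr(df["a"], df["b"]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(df["a"], df["b"]).statistic)
    raise ValueError(f"unknown method {method!r}")


def seasonal_consistency(
    spring: PopulationSeries,
    autumn: PopulationSeries,
    method: str = "pearson",
) -> float:
    """Correlation of spring and autumn censuses over their common years
    -- high values justify mixing counting seasons in one series."""
    df = _paired(spring.year, spring.count, autumn.year, autumn.count)
    if len(df) < 3:
        raise ValueError(f"only {len(df)} common years; at least 3 required")
    if method == "pearson":
        return float(stats.pearsonr(df["a"], df["b"]).statistic)
    if method == "spearman":
        return float(stats.spearmanr(df["a"], df["b"]).statistic)
    raise ValueError(f"unknown method {method!r}")
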