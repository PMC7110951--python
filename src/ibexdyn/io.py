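"""CSV readers/writers and run configuration.

File dialects (header row required, UTF-8, one row per year):

* census:  ``year,count[,season]``
* climate: ``year,winter_precip_mm``
* wardens: ``year,wardens``

Ensemble summaries carry both the raw continuous values and their
rounded integer counterparts: simulation keeps counts continuous to
avoid rounding bias, and rounds only at serialisation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import EnsembleForecast, FittedModel, ValidationReport
from .series import ClimateSeries, PopulationSeries, WardenSeries

__all__ = [
    "RunConfig",
    "read_series",
    "write_forecast",
    "read_forecast_summary",
    "write_validation",
    "write_metadata",
    "write_model",
    "read_model",
]

_SCHEMAS = {
    "census": ("year", "count"),
    "climate": ("year", "winter_precip_mm"),
    "wardens": ("year", "wardens"),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, so two runs with the same
    config are byte-identical."""

    census: str | None = None
    climate: str | None = None
    variant: str = "D2"
    train_start: int | None = None
    train_end: int | None = None
    n_real: int = 1000
    band_level: float = 0.90
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if not 0 < self.band_level < 1:
            raise ValueError("band_level must be in (0, 1)")
        if self.n_real < 2:
            raise ValueError("n_real must be at least 2")

    def echo(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after the header
        raise ValueError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"'{col}', row {row}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0]) + 2
        raise ValueError(f"{path}: empty cell in column '{col}', row {row}")
    return vals.to_numpy()


def read_series(path, kind: str):
    """Read and validate a census, climate or wardens CSV.

    Distinct errors for a schema mismatch, a duplicate year, a
    non-numeric cell (with its row number) and a negative value.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"kind must be one of {tuple(_SCHEMAS)}, got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: schema mismatch for kind '{kind}': missing column(s) "
            f"{', '.join(missing)} (found: {', '.join(df.columns)})"
        )
    years = _numeric_column(df, "year", path).astype(np.int64)
    dup = pd.Series(years).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate year {years[dup.to_numpy()][0]}")
    values = _numeric_column(df, required[1], path)
    order = np.argsort(years)
    years, values = years[order], values[order]
    if np.any(values < 0):
        bad = years[values < 0][0]
        raise ValueError(f"{path}: negative {required[1]} in year {bad}")
    if kind == "census":
        season = None
        if "season" in df.columns and df["season"].notna().any():
            labels = set(df["season"].dropna().unique())
            if len(labels) == 1:
                season = labels.pop()
        return PopulationSeries(years, values, season=season)
    if kind == "climate":
        return ClimateSeries(years, values)
    return WardenSeries(years, values)


def write_forecast(forecast: EnsembleForecast, path) -> None:
    """Ensemble summary CSV: per-year mean and band (raw and rounded),
    plus the run constants (n_real, band_level, seed)."""
    df = pd.DataFrame(
        {
            "year": forecast.years,
            "mean": forecast.mean_traj,
            "band_lower": forecast.band_lower,
            "band_upper": forecast.band_upper,
            "mean_rounded": np.round(forecast.mean_traj).astype(np.int64)
            if forecast.years.size else np.array([], dtype=np.int64),
            "band_lower_rounded": np.round(forecast.band_lower).astype(np.int64)
            if forecast.years.size else np.array([], dtype=np.int64),
            "band_upper_rounded": np.round(forecast.band_upper).astype(np.int64)
            if forecast.years.size else np.array([], dtype=np.int64),
            "n_real": forecast.n_real,
            "band_level": forecast.band_level,
            "seed": forecast.seed,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_forecast_summary(path) -> pd.DataFrame:
    """Round-trip reader for the ensemble summary CSV."""
    return pd.read_csv(path)


def write_validation(report: ValidationReport, path) -> None:
    """Validation CSV: year, observed count, inside-band flag, and a
    marker on the first exit year (the alarm bell)."""
    first_exit = (
        report.years == report.first_exit_year
        if report.first_exit_year is not None
        else np.zeros(report.years.size, dtype=bool)
    )
    df = pd.DataFrame(
        {
            "year": report.years,
            "observed": report.observed,
            "inside": report.inside,
            "first_exit": first_exit,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_model(model: FittedModel, path) -> None:
    """Fitted-model YAML: variant, coefficients, sigma, window, n_obs."""
    doc = {
        "variant": model.variant,
        "a": float(model.a), "b": float(model.b),
        "c": float(model.c), "d": float(model.d),
        "sigma": float(model.sigma),
        "train_window": [int(model.train_window[0]), int(model.train_window[1])],
        "n_obs": int(model.n_obs),
    }
    if model.col_mean is not None:
        doc["col_mean"] = [float(v) for v in model.col_mean]
        doc["col_scale"] = [float(v) for v in model.col_scale]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_model(path) -> FittedModel:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return FittedModel(
        variant=doc["variant"], a=doc["a"], b=doc["b"], c=doc["c"], d=doc["d"],
        sigma=doc["sigma"], train_window=tuple(doc["train_window"]),
        n_obs=doc["n_obs"],
        col_mean=np.array(doc["col_mean"]) if "col_mean" in doc else None,
        col_scale=np.array(doc["col_scale"]) if "col_scale" in doc else None,
    )


def write_metadata(path, **fields) -> None:
    """Config echo as a small YAML key:value file (variant, window, seed,
    quantile method, row counts ...)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(fields, fh, sort_keys=True)
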