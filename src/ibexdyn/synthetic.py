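"""Synthetic census, climate, warden and intervention series.

The historical archives behind the analysis (interwar censuses, valley
meteorological stations, warden rosters) are not deposited anywhere, so
this module generates series with the same statistical structure: an
annual count driven by the stochastic density + climate log-growth model,
a winter precipitation series with realistic interannual variance, an
optional anthropogenic removal switched on at a changepoint year, an
optional founder-population regime (low initial density, near-exponential
growth), and optional census gaps.

The default ``ScenarioSpec`` is calibrated to the interwar regime the
analysis targets -- a colony of ~2400 animals growing at ~10%/yr towards
a ~3500-head quasi-equilibrium over a 20-year window, forced by winter
totals around 400 mm -- and those numbers are calibration choices of this
package, not archival values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .model import EXTINCTION_THRESHOLD, FittedModel, step
from .series import ClimateSeries, PopulationSeries, WardenSeries

__all__ = [
    "ScenarioSpec",
    "founder_scenario",
    "generate_climate",
    "generate_census",
    "generate_wardens",
    "child_seeds",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator derived from one integer seed by a fixed offset key,
    so every experiment is reproducible from a single seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def child_seeds(seed: int, n: int) -> np.ndarray:
    """``n`` independent 31-bit child seeds derived from one master seed.

    Replicate experiments draw their per-replicate scenario seeds from
    here, so a whole simulation study is reproducible from one integer.
    """
    state = np.random.SeedSequence(seed).generate_state(n, np.uint32)
    return (state & np.uint32(0x7FFFFFFF)).astype(np.int64)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for one synthetic study.

    ``a, b, c, d`` are the true log-growth coefficients of the chosen
    variant and ``sigma`` the process-noise standard deviation.  When
    ``changepoint_year`` is set, an anthropogenic removal of
    ``removal_rate`` (a fraction per year, modelling poaching or harvest
    as a survival factor) is applied to every year after it.
    ``gap_years`` are deleted from the emitted census only, emulating
    missing censuses; the latent trajectory is unaffected.
    """

    variant: str = "D2"
    a: float = 2.21
    b: float = -0.23
    c: float = -0.0005  # per mm of winter precipitation
    d: float = -0.00004  # density x precipitation interaction
    sigma: float = 0.08
    N0: float = 2370.0
    start_year: int = 1922
    n_years: int = 20
    climate_mean: float = 400.0  # mm per winter
    climate_sd: float = 100.0
    changepoint_year: int | None = None
    removal_rate: float = 0.0
    founder: bool = False
    gap_years: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if not 0 <= self.removal_rate < 1:
            raise ValueError("removal_rate must be in [0, 1)")
        if self.climate_mean <= 0 or self.climate_sd < 0:
            raise ValueError("climate_mean must be positive, climate_sd non-negative")
        if self.changepoint_year is not None:
            last = self.start_year + self.n_years
            if not self.start_year < self.changepoint_year <= last:
                raise ValueError(
                    f"changepoint_year {self.changepoint_year} outside the "
                    f"simulated window {self.start_year + 1}-{last}"
                )

    def true_model(self) -> FittedModel:
        """The data-generating process packaged as a FittedModel (the
        training-window fields are nominal)."""
        return FittedModel(
            variant=self.variant, a=self.a, b=self.b, c=self.c, d=self.d,
            sigma=self.sigma,
            train_window=(self.start_year, self.start_year + self.n_years),
            n_obs=max(self.n_years, 5),
        )

    def with_(self, **changes) -> "ScenarioSpec":
        return replace(self, **changes)


def d1_scenario(**overrides) -> ScenarioSpec:
    """Default truth for the raw-density variant.  The density slope is
    per *head* rather than per log-head, so the coefficients are rescaled
    to put the same ~3500-animal equilibrium and ~8%/yr initial growth on
    the D1 covariate scale."""
    base = dict(variant="D1", a=0.445, b=-5e-5, c=-0.0005, d=-5e-8)
    base.update(overrides)
    return ScenarioSpec(**base)


def founder_scenario(**overrides) -> ScenarioSpec:
    """A reintroduced colony far below carrying capacity: a handful of
    founders whose growth is near-exponential because the density terms
    are negligible at low numbers (the Swiss-park comparison case)."""
    base = dict(N0=25.0, n_years=20, sigma=0.05)
    base.update(overrides)
    return ScenarioSpec(**base)


def generate_climate(spec: ScenarioSpec) -> ClimateSeries:
    """I.i.d. truncated-at-zero Gaussian winter totals.

    One value per simulated winter, for the winters ending in
    ``start_year + 1 .. start_year + n_years``.  Winters are treated as
    exchangeable (no autocorrelation model).
    """
    years = np.arange(spec.start_year + 1, spec.start_year + spec.n_years + 1)
    if spec.climate_sd == 0:
        precip = np.full(years.size, spec.climate_mean)
    else:
        a = (0.0 - spec.climate_mean) / spec.climate_sd
        precip = stats.truncnorm.rvs(
            a, np.inf, loc=spec.climate_mean, scale=spec.climate_sd,
            size=years.size, random_state=_rng(spec.seed, 1),
        )
    return ClimateSeries(years, precip)


def generate_census(
    spec: ScenarioSpec, clim: ClimateSeries
) -> tuple[PopulationSeries, PopulationSeries]:
    """Forward-simulate the census and its latent no-intervention twin.

    Both series start from ``N0`` in ``start_year`` and share the same
    noise draws, so they differ only after ``changepoint_year``: from the
    first year after the changepoint onwards the observed count is the
    stepped count multiplied by ``(1 - removal_rate)``, and that reduced
    count is the state the next step starts from (removed animals do not
    reproduce).  ``gap_years`` are dropped from the observed output only.

    Returns ``(observed, latent_twin)``.
    """
    years = np.arange(spec.start_year, spec.start_year + spec.n_years + 1)
    missing = years[1:][~clim.covers(years[1:])]
    if missing.size:
        raise ValueError(
            f"climate series missing years: {', '.join(map(str, missing))}"
        )
    model = spec.true_model()
    rng = _rng(spec.seed, 2)
    eps = rng.normal(0.0, spec.sigma, size=years.size - 1)
    obs = np.empty(years.size)
    latent = np.empty(years.size)
    obs[0] = latent[0] = spec.N0
    for j, y in enumerate(years[1:]):
        P = clim.at(int(y))
        latent[j + 1] = step(model, latent[j], P, eps[j])
        n = step(model, obs[j], P, eps[j])
        if spec.changepoint_year is not None and y > spec.changepoint_year:
            n *= 1.0 - spec.removal_rate
            if n < EXTINCTION_THRESHOLD:
                n = 0.0
        obs[j + 1] = n
    observed = PopulationSeries(years, obs)
    if spec.gap_years:
        observed = observed.drop_years(spec.gap_years)
    return observed, PopulationSeries(years, latent)


def generate_wardens(
    n_years: int,
    base: int = 40,
    drop_year: int | None = 1934,
    drop_size: int = 16,
    seed: int = 0,
    start_year: int = 1922,
    jitter: int = 1,
) -> WardenSeries:
    """A stable warden headcount with a step drop (mass dismissal) at
    ``drop_year``, plus small integer jitter.  ``base`` must exceed
    ``drop_size`` (the corps never disappears entirely)."""
    if not base > drop_size >= 0:
        raise ValueError("need base > drop_size >= 0")
    years = np.arange(start_year, start_year + n_years)
    level = np.full(years.size, float(base))
    if drop_year is not None:
        level[years >= drop_year] -= drop_size
    if jitter > 0:
        level = level + _rng(seed, 3).integers(-jitter, jitter + 1, size=years.size)
    return WardenSeries(years, np.maximum(level, 0.0))
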