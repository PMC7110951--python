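"""Stochastic log-growth population model with density dependence and
winter-climate forcing.

The model describes the annual log growth rate of a census series

    r_t = ln(N_t / N_{t-1}) = a + b*D_{t-1} + c*P_t + d*D_{t-1}*P_t + eps_t

where ``D`` is the density covariate -- the raw count for variant D1, its
natural logarithm for variant D2 (the park area is constant, so count is
proportional to density) -- ``P_t`` is the total precipitation of the
winter ending in year ``t`` (a snow-depth proxy, mm), and ``eps_t`` is
i.i.d. Gaussian process noise.  The growth rate is attributed to the
interval's *ending* year: the winter ending in year ``t`` forces the
growth from the year ``t-1`` count to the year ``t`` count.

The workflow is: fit the four coefficients by ordinary least squares on a
training window, simulate an ensemble of stochastic forward trajectories,
summarise them with per-year empirical quantile bands, and validate later
observed censuses against the band.  The first year an observation leaves
the band is the "alarm bell": from that point onwards the dynamics can no
longer be explained by density and climate alone, and non-ecological
causes (harvest, poaching, collapse of surveillance) must be invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .series import ClimateSeries, PopulationSeries

__all__ = [
    "VARIANTS",
    "EXTINCTION_THRESHOLD",
    "COLUMN_NAMES",
    "SingularFitError",
    "TooFewObservationsError",
    "FittedModel",
    "EnsembleForecast",
    "ValidationReport",
    "growth_rates",
    "design_row",
    "fit_model",
    "step",
    "simulate_ensemble",
    "validate_out_of_sample",
    "first_band_exit",
]

VARIANTS = ("D1", "D2")

#: simulated populations below one animal are extinct (absorbing state)
EXTINCTION_THRESHOLD = 1.0

COLUMN_NAMES = ("intercept", "density", "precip", "density_x_precip")

_MIN_OBS = 5  # fewer observations than this for a 4-parameter fit is rejected


class SingularFitError(ValueError):
    """Design matrix is rank deficient (a covariate is collinear)."""


class TooFewObservationsError(ValueError):
    """Not enough growth-rate observations for a 4-parameter fit."""


def _check_variant(variant: str) -> str:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    return variant


def growth_rates(pop: PopulationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Log growth rates of consecutive-year census pairs.

    Returns ``(years, r)`` where ``r[i] = ln(N_{years[i]} / N_{years[i]-1})``;
    each rate is attributed to the ending year of its interval.  Pairs that
    span a gap in the series (a missing year) are skipped, never
    interpolated.  The result is empty when no consecutive pair exists.

    Raises
    ------
    ValueError
        If a count involved in a consecutive pair is zero (the log is
        undefined; extinction must be handled upstream).
    """
    years, counts = pop.year, pop.count
    if years.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    consec = np.diff(years) == 1
    if np.any(consec & ((counts[:-1] <= 0) | (counts[1:] <= 0))):
        bad = years[1:][consec & ((counts[:-1] <= 0) | (counts[1:] <= 0))][0]
        raise ValueError(
            f"zero count in the consecutive pair ending {bad}: log growth undefined"
        )
    r = np.log(counts[1:][consec] / counts[:-1][consec])
    return years[1:][consec], r


def design_row(variant: str, N_prev: float, P: float) -> np.ndarray:
    """Covariate row ``(1, D, P, D*P)`` with ``D = N_prev`` (D1) or
    ``ln N_prev`` (D2).  ``N_prev`` must be positive, ``P`` non-negative."""
    _check_variant(variant)
    if N_prev <= 0:
        raise ValueError(f"previous count must be positive, got {N_prev}")
    if P < 0:
        raise ValueError(f"precipitation must be non-negative, got {P}")
    D = np.log(N_prev) if variant == "D2" else float(N_prev)
    return np.array([1.0, D, P, D * P])


def _design_matrix(variant: str, N_prev: np.ndarray, P: np.ndarray) -> np.ndarray:
    D = np.log(N_prev) if variant == "D2" else np.asarray(N_prev, dtype=float)
    return np.column_stack([np.ones_like(D), D, P, D * P])


def _find_collinear_column(X: np.ndarray) -> str:
    """Name the first column that is (numerically) a linear combination of
    the previous ones."""
    for j in range(1, X.shape[1]):
        coef, *_ = np.linalg.lstsq(X[:, :j], X[:, j], rcond=None)
        resid = X[:, j] - X[:, :j] @ coef
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            return COLUMN_NAMES[j]
    return "unknown"


@dataclass(frozen=True)
class FittedModel:
    """A fitted log-growth model: variant tag, four coefficients, the
    residual standard deviation of the log growth rate, and the training
    window it came from.

    When the model was fitted with covariate standardisation, ``col_mean``
    and ``col_scale`` record the centring/scaling applied to the three
    non-constant design columns; prediction re-applies the same transform,
    so a standardised and an unstandardised fit predict identically.
    """

    variant: str
    a: float  # intercept, per-year log growth
    b: float  # density coefficient
    c: float  # precipitation coefficient, per mm
    d: float  # density x precipitation interaction
    sigma: float  # residual sd of the log growth rate
    train_window: tuple[int, int]
    n_obs: int
    col_mean: np.ndarray | None = field(default=None, compare=False)
    col_scale: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        _check_variant(self.variant)
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_obs < _MIN_OBS:
            raise TooFewObservationsError(
                f"{self.n_obs} growth observations; at least {_MIN_OBS} required"
            )

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])

    def log_growth(self, N_prev, P) -> np.ndarray:
        """Deterministic part of the log growth rate (vectorised over
        positive previous counts)."""
        N_prev = np.atleast_1d(np.asarray(N_prev, dtype=float))
        P = np.broadcast_to(np.asarray(P, dtype=float), N_prev.shape)
        D = np.log(N_prev) if self.variant == "D2" else N_prev
        cols = np.stack([D, P, D * P])
        if self.col_mean is not None:
            cols = (cols - self.col_mean[:, None]) / self.col_scale[:, None]
        return self.a + self.b * cols[0] + self.c * cols[1] + self.d * cols[2]


def fit_model(
    pop: PopulationSeries,
    clim: ClimateSeries,
    variant: str,
    train_window: tuple[int, int],
    standardize: bool = False,
) -> FittedModel:
    """Fit the log-growth model by ordinary least squares.

    Growth rates within ``train_window`` (endpoints inclusive, attributed
    to the ending year of each interval) are regressed on
    ``(1, D, P, D*P)``.  ``sigma`` is ``sqrt(RSS / (n_obs - 4))``.

    Raises
    ------
    TooFewObservationsError
        Fewer than 5 usable (growth rate, covariate) pairs.
    SingularFitError
        Rank-deficient design, naming the collinear column (e.g. constant
        precipitation makes the precip column collinear with the
        intercept).
    KeyError
        A growth year has no matching climate value.
    """
    _check_variant(variant)
    first, last = int(train_window[0]), int(train_window[1])
    if first < pop.year.min() or last > pop.year.max():
        raise ValueError(
            f"train window {first}-{last} extends beyond the census series "
            f"{pop.year.min()}-{pop.year.max()}"
        )
    g_years, r = growth_rates(pop.window(first, last))
    if g_years.size < _MIN_OBS:
        raise TooFewObservationsError(
            f"{g_years.size} usable growth observations in {first}-{last}; "
            f"at least {_MIN_OBS} required"
        )
    N_prev = np.array([pop.at(int(y) - 1) for y in g_years])
    P = np.array([clim.at(int(y)) for y in g_years])
    X = _design_matrix(variant, N_prev, P)
    if np.linalg.matrix_rank(X) < 4:
        raise SingularFitError(
            f"singular design: column '{_find_collinear_column(X)}' is "
            "collinear with the others"
        )
    col_mean = col_scale = None
    if standardize:
        col_mean = X[:, 1:].mean(axis=0)
        col_scale = X[:, 1:].std(axis=0, ddof=0)
        X = X.copy()
        X[:, 1:] = (X[:, 1:] - col_mean) / col_scale
    res = sm.OLS(r, X).fit()
    sigma = float(np.sqrt(res.ssr / (g_years.size - 4)))
    a, b, c, d = (float(v) for v in res.params)
    return FittedModel(
        variant=variant, a=a, b=b, c=c, d=d, sigma=sigma,
        train_window=(first, last), n_obs=int(g_years.size),
        col_mean=col_mean, col_scale=col_scale,
    )


def step(model: FittedModel, N_t: float, P_next: float, eps: float = 0.0) -> float:
    """One-year update ``N_{t+1} = N_t * exp(r + eps)``.

    Populations below the extinction threshold (one animal) are absorbed
    at zero: extinction is a state, not an error.
    """
    if N_t < 0:
        raise ValueError("count must be non-negative")
    if N_t < EXTINCTION_THRESHOLD:
        return 0.0
    r = model.log_growth(N_t, P_next).item()
    return float(N_t * np.exp(r + eps))


def _step_ensemble(model: FittedModel, N: np.ndarray, P: float, eps: np.ndarray) -> np.ndarray:
    alive = N >= EXTINCTION_THRESHOLD
    out = np.zeros_like(N)
    if np.any(alive):
        Na = N[alive]
        out[alive] = Na * np.exp(model.log_growth(Na, P) + eps[alive])
    return out


@dataclass(frozen=True)
class EnsembleForecast:
    """A Monte-Carlo ensemble of forward trajectories and its per-year
    summary: the ensemble mean and the empirical quantile band that holds
    ``band_level`` of the realizations (90% in the reference protocol)."""

    years: np.ndarray
    realizations: np.ndarray  # (n_real, n_years)
    mean_traj: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    n_real: int
    seed: int
    band_level: float
    quantile_method: str = "linear"

    def __post_init__(self):
        if self.years.size and np.any(self.band_lower > self.band_upper):
            raise ValueError("band_lower must not exceed band_upper")


def simulate_ensemble(
    model: FittedModel,
    N_start: float,
    start_year: int,
    clim: ClimateSeries,
    n_real: int = 1000,
    seed: int = 0,
    band_level: float = 0.90,
    end_year: int | None = None,
) -> EnsembleForecast:
    """Simulate ``n_real`` stochastic trajectories from ``N_start``.

    Forecast years run from ``start_year + 1`` to ``end_year`` (default:
    the last climate year); every forecast year needs a climate value.
    Noise draws are i.i.d. Normal(0, sigma) across years and realizations,
    drawn up front from a single seeded generator, so an identical
    ``(model, seed, climate)`` triple gives a bit-identical ensemble and
    the trajectories respond monotonically to climate shifts under a fixed
    seed.  Bands are per-year empirical quantiles at ``(1 - L)/2`` and
    ``1 - (1 - L)/2`` (linear interpolation of order statistics).
    """
    if n_real < 2:
        raise ValueError("n_real must be at least 2")
    if not 0 < band_level < 1:
        raise ValueError("band_level must be in (0, 1)")
    if end_year is None:
        end_year = int(clim.year.max())
    years = np.arange(start_year + 1, end_year + 1, dtype=np.int64)
    missing = years[~clim.covers(years)]
    if missing.size:
        raise ValueError(
            f"climate series missing forecast years: {', '.join(map(str, missing))}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eps = rng.normal(0.0, model.sigma, size=(n_real, years.size))
    realizations = np.empty((n_real, years.size))
    N = np.full(n_real, float(N_start))
    for j, y in enumerate(years):
        N = _step_ensemble(model, N, clim.at(int(y)), eps[:, j])
        realizations[:, j] = N
    alpha = (1.0 - band_level) / 2.0
    if years.size:
        lower = np.quantile(realizations, alpha, axis=0, method="linear")
        upper = np.quantile(realizations, 1.0 - alpha, axis=0, method="linear")
        mean = realizations.mean(axis=0)
    else:
        lower = upper = mean = np.empty(0)
    return EnsembleForecast(
        years=years, realizations=realizations, mean_traj=mean,
        band_lower=lower, band_upper=upper, n_real=n_real, seed=seed,
        band_level=band_level,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Out-of-sample comparison of observed censuses against the band.

    ``coverage`` is the fraction of validated years whose observation lies
    inside the closed band; ``first_exit_year`` is the earliest year with
    an observation outside it (the alarm bell), or ``None``.  An empty
    report (no validated years) has ``coverage`` NaN.
    """

    years: np.ndarray
    observed: np.ndarray
    inside: np.ndarray
    coverage: float
    first_exit_year: int | None

    @classmethod
    def empty(cls) -> "ValidationReport":
        return cls(
            years=np.empty(0, dtype=np.int64), observed=np.empty(0),
            inside=np.empty(0, dtype=bool), coverage=float("nan"),
            first_exit_year=None,
        )


def validate_out_of_sample(
    forecast: EnsembleForecast, observed: PopulationSeries
) -> ValidationReport:
    """Flag each observed year as inside or outside the forecast band.

    The band is closed: an observation exactly on the edge counts as
    inside, so a zero-noise model never false-alarms on its own mean.
    Years without an observation (the 1944-style census gap) are simply
    skipped.  Raises ``ValueError`` when no observed year intersects the
    forecast.
    """
    mask = np.isin(forecast.years, observed.year)
    if not np.any(mask):
        raise ValueError("no observed year falls inside the forecast window")
    years = forecast.years[mask]
    obs = np.array([observed.at(int(y)) for y in years])
    inside = (obs >= forecast.band_lower[mask]) & (obs <= forecast.band_upper[mask])
    exits = years[~inside]
    return ValidationReport(
        years=years, observed=obs, inside=inside,
        coverage=float(inside.mean()),
        first_exit_year=int(exits[0]) if exits.size else None,
    )


def first_band_exit(report: ValidationReport) -> int | None:
    """The alarm bell: the earliest validated year whose observation lies
    outside the band, or ``None`` when the observations never leave it."""
    return report.first_exit_year
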