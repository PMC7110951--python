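from pathlib import Path

import numpy as np
import pytest

import ibexdyn as ib

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_census() -> ib.PopulationSeries:
    """8-year census fixture shipped in the repo."""
    return ib.read_series(DATA / "toy_census.csv", "census")


@pytest.fixture(scope="session")
def toy_climate() -> ib.ClimateSeries:
    return ib.read_series(DATA / "toy_climate.csv", "climate")


@pytest.fixture(scope="session")
def default_spec() -> ib.ScenarioSpec:
    """The package's interwar-like calibration (ground truth for
    round-trip and protocol tests)."""
    return ib.ScenarioSpec()


@pytest.fixture(scope="session")
def generated(default_spec):
    """A no-intervention synthetic study: (spec, climate, observed, latent)."""
    spec = default_spec.with_(seed=42)
    clim = ib.generate_climate(spec)
    obs, latent = ib.generate_census(spec, clim)
    return spec, clim, obs, latent


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force OLS oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="session")
def ols_oracle():
    return normal_equations


def random_fit_instance(rng: np.random.Generator, variant: str):
    """A random full-rank (pop, clim, window) fitting problem with
    5 <= n_obs <= 50 growth observations."""
    n_obs = int(rng.integers(5, 51))
    start = 1900 + int(rng.integers(0, 50))
    years = np.arange(start, start + n_obs + 1)
    counts = rng.uniform(50, 5000, size=n_obs + 1)
    precip = rng.uniform(100, 800, size=n_obs)
    pop = ib.PopulationSeries(years, counts)
    clim = ib.ClimateSeries(years[1:], precip)
    return pop, clim, (start, start + n_obs)
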