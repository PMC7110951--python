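# Methods

## Model and estimation

The state variable is the annual census count `N_t` (continuous inside
simulations; the park area is constant, so count is proportional to
density). The log growth rate `r_t = ln(N_t / N_{t-1})` is linear in an
intercept, a density covariate `D_{t-1}` (raw count for variant D1,
natural log of the count for D2), the winter precipitation total `P_t`
(mm, November–April, attributed to the calendar year the winter ends
in), and the product `D_{t-1}·P_t`, plus i.i.d. Gaussian process noise.
The alignment convention — the winter ending in year `t` forces the
growth from the year `t−1` count to the year `t` count, and `r` is
attributed to the interval's ending year — is a package decision; the
covariate structure itself admits no other causally sensible phasing.

Estimation is ordinary least squares on the growth rates of a training
window (via statsmodels); `σ` is `sqrt(RSS/(n−4))`. At least five
growth observations are required for the four-parameter fit, and a
rank-deficient design (e.g. constant precipitation) raises an error
naming the collinear column. Growth pairs spanning a census gap are
dropped, never interpolated. Covariates are not standardized by
default — this keeps the brute-force normal-equations cross-check exact
— but `standardize=True` centres and scales the three non-constant
columns and stores the transform on the model, which then predicts
identically to the raw fit.

## Simulation, bands, and the alarm bell

Forecasts iterate the multiplicative one-step update
`N_{t+1} = N_t · exp(r + ε)` with `ε ~ N(0, σ²)` drawn independently
across years and realizations. All noise for an ensemble is drawn up
front from one seeded generator (`numpy` PCG64 via `SeedSequence`), so
an ensemble is bit-reproducible from its seed and responds monotonically
to climate shifts under a fixed seed. Counts below 1.0 animal are
absorbed at zero: extinction is a state, not an error. Simulated counts
stay continuous to avoid rounding bias and are rounded only at
serialisation (both raw and rounded columns are written).

Bands are per-year empirical quantiles of the realization matrix at
`(1±L)/2` for band level `L` (default 0.90, ensemble size default
1 000), using linear interpolation of order statistics; with 1 000
realizations this puts at most 50 realizations strictly outside each
edge, i.e. at least 900 inside the closed band every year. Validation
flags each observed year as inside the *closed* band (an observation on
the edge counts as inside, so a zero-noise model never false-alarms on
its own mean); unobserved years are skipped. The first outside year is
the alarm bell. An empty validation (no overlapping years) is an error
in `validate_out_of_sample` but a graceful degenerate case in
`run_windowed` (coverage NaN, no exit).

A caveat worth stating: per-year coverage and trajectory-wise exit
rarity are different quantities. The band is calibrated per year (mean
coverage within a few points of 90 % under self-validation), but the
probability that a trajectory *never* leaves the band decays with the
horizon even for a perfectly calibrated band — roughly half of
10-year-horizon replicates see at least one single-year excursion.
Alarm-bell conclusions should therefore rest on the location of the
first exit relative to a hypothesised changepoint (and on its
persistence), not on the bare existence of an exit far into the
forecast.

## Synthetic study conditions

The generator's defaults encode the study regime, chosen once as
calibration (they are not archival values): D2 truth `a = 2.21`,
`b = −0.23`, `c = −5·10⁻⁴ /mm`, `d = −4·10⁻⁵ /mm`, `σ = 0.08`,
`N0 = 2370`, 20 simulated years from 1922, winter totals
truncated-Gaussian with mean 400 mm and sd 100 mm. This yields ~10 %/yr
initial growth decelerating toward a ≈3 500-head quasi-equilibrium and a
climate contribution of roughly ±8 % growth per one-sd winter —
consistent with the interwar record's shape and with log-growth
residual scatter reported for Alpine ungulates. The D1 preset
(`d1_scenario`) re-expresses the same equilibrium and growth on the
raw-count covariate scale (`a = 0.445`, `b = −5·10⁻⁵`, `d = −5·10⁻⁸`).
The founder preset starts 25 animals far below carrying capacity, where
the density terms are negligible and growth is near-exponential.

Interventions are a survival fraction: after the changepoint year each
stepped count is multiplied by `(1 − removal_rate)`, and the reduced
count is the state the next step starts from — removed animals do not
reproduce, so the removal interacts with density dependence (partial
demographic compensation). The latent no-intervention twin shares the
same noise draws and differs only after the changepoint. Census gaps
delete rows from the emitted series only. Winters are exchangeable
(no autocorrelation model, no separate snow-depth process, no
liquid/solid partitioning); one-off emigration pulses are not modelled.

What the generator does **not** emulate: observation error in the
counts (censuses enter as truth), age/sex structure, spatial structure,
density-independent catastrophes, and climate trends. Passing tests
therefore demonstrate the internal consistency and calibration of the
method under its own assumptions, not the fidelity of any historical
series.

## Replicate studies and problem sizes

Three scripted studies (`ibexdyn.studies`) characterise the protocol,
all child-seeded from one master integer so every run is reproducible:

* **recovery_study** — 500 replicate refits at 50 and 100 years; the
  median absolute error of every coefficient drops when the series
  doubles (consistency; the near-collinearity of `P` and `D·P` around
  equilibrium makes the climate coefficients individually noisy, which
  is why the check is on medians and trends, not fixed bounds).
* **coverage_study** — 500 replicates of fit → draw a fresh pseudo-
  observed path *from the fitted model* → validate against the fitted
  model's own 1 000-member band over a 10-year horizon; mean per-year
  coverage sits within 3 points of 90 %. Self-validation isolates band
  bookkeeping from parameter-estimation error; validating against the
  *true* model instead costs ~10 points of coverage at these window
  lengths, a plug-in-band effect, not a bug.
* **detection_study** — 200 replicates per removal strength; removal
  starts at the first forecast year τ (right after a 20-year fit
  window) and the hit criterion is a first exit inside [τ, τ+3].
  Detection is ≈100 % at 20 %/yr and declines smoothly with weaker
  removal, monotone over {5, 10, 20} %.

These sizes (20-year fit windows, 10-year horizons, 200–500 replicates,
1 000-member ensembles) are the package's chosen experiment scale; the
whole acceptance script completes in seconds.

## Numerical choices

* Quantile method: `numpy` "linear" (recorded in output metadata).
* Band-edge ties count as inside.
* Extinction threshold 1.0 animal, absorbing.
* `σ` denominator `n − 4`; fits reject `n < 5`.
* Collinearity diagnosis: sequential least-squares projection of each
  design column on its predecessors, first numerically dependent column
  is named.
* Child seeds: 31-bit integers from `SeedSequence(master).generate_state`,
  or spawn-key offsets for the generator streams; no global RNG state is
  ever touched.

## Known limitations

Prediction bands ignore parameter uncertainty (plug-in bands), so
out-of-sample coverage against nature is below nominal for short
training windows; a parametric-bootstrap band would widen them at the
cost of the exact OLS cross-check. The estimator assumes homoscedastic
Gaussian log-growth noise; heavy-tailed disturbance years (epizootics,
extreme winters beyond the linear range) will both inflate `σ` and
trigger exits that are ecological rather than anthropogenic — the alarm
bell flags *unexplained* dynamics, it does not attribute them.
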