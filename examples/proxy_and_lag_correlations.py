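"""Descriptive analyses: station averaging, proxy R², and lagged
warden-census correlation.

Three synthetic valley stations measure the same regional winter signal
with station-specific noise; their average is validated as a proxy
against the cleanest station.  A warden headcount with a mass dismissal
is then correlated (at a 1-year lag, in first differences) with a census
whose changes echo the staffing changes.
"""

import numpy as np

import ibexdyn as ib

rng = np.random.default_rng(31)
years = np.arange(1922, 1939)
regional = rng.normal(400.0, 90.0, years.size).clip(min=50)

stations = [
    ib.ClimateSeries(years, (regional + rng.normal(0, 60, years.size)).clip(min=0))
    for _ in range(3)
]
avg = ib.station_average(stations)
print(f"three-station average over {avg.year[0]}-{avg.year[-1]}, "
      f"contributors per year: {set(avg.n_stations.tolist())}")

target = ib.ClimateSeries(years, (regional + rng.normal(0, 40, years.size)).clip(min=0))
rep = ib.proxy_correlation(avg, target)
print(f"R^2(average, high-altitude target) = {rep.r_squared:.2f} "
      f"over {rep.n_pairs} winters")
print("An R^2 well above 0.5 says the averaged valley stations track the "
      "signal the model needs.\n")

# wardens: stable corps, 16 dismissed in 1934; census changes echo
# staffing changes one year later
wardens = ib.generate_wardens(17, base=40, drop_year=1934, drop_size=16,
                              seed=32, start_year=1922, jitter=1)
dw = np.diff(wardens.wardens)
counts = np.empty(years.size)
counts[0] = 3000
for t in range(1, years.size):
    echo = 40.0 * dw[t - 2] if t >= 2 else 0.0
    counts[t] = counts[t - 1] + echo + rng.normal(0, 30)
census = ib.PopulationSeries(years, counts.clip(min=100))

for lag in (0, 1, 2):
    c = ib.lagged_correlation(wardens, census, lag=lag)
    print(f"lag-{lag} correlation of changes: {c:+.2f}")
print("The correlation peaking at lag 1 reproduces the signature of "
      "census changes following staffing changes with a one-year delay.")
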