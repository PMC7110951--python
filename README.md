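# ibexdyn

Stochastic density-dependence + climate-forcing population dynamics for
annual wildlife census series — fit, forecast, validate, and use the
forecast band as an **alarm bell** for non-ecological causes of decline.

The package grew out of a classic question in historical ecology: the
Alpine ibex (*Capra ibex*) colony of the Gran Paradiso massif grew from
about 2 400 to about 3 900 animals between the early 1920s and the
mid-1930s, then collapsed. Can density dependence and winter climate
alone explain the collapse, or must anthropogenic causes (poaching, the
breakdown of warden surveillance) be invoked — and from which year
onwards? The same machinery applies to any annual census series with an
environmental covariate.

## The model

The annual log growth rate of the census `N_t` is modelled as

```
r_t = ln(N_t / N_{t-1}) = a + b·D_{t-1} + c·P_t + d·D_{t-1}·P_t + ε_t,
ε_t ~ N(0, σ²) i.i.d.
```

where `D` is the density covariate — the raw count (variant **D1**) or
its natural log (variant **D2**) — and `P_t` is the total November–April
precipitation of the winter ending in year `t` (a snow-depth proxy, mm).
The four coefficients are estimated by ordinary least squares on a
training window; `σ` is the residual standard deviation (denominator
`n − 4`). The fitted model is then run forward as a stochastic ensemble
(1 000 realizations by default); per-year empirical quantiles give a 90 %
prediction band; later censuses are validated against the band, and the
**first band exit** marks the year from which density and climate stop
explaining the record. Populations below one animal are absorbed at
zero (extinction).

Because the historical archives are not deposited anywhere, the package
ships a first-class synthetic generator (`ScenarioSpec`,
`generate_climate`, `generate_census`, `generate_wardens`) that emulates
the study conditions: a ~20-year census driven by the model above,
truncated-Gaussian winter totals, an optional removal intervention
switched on at a changepoint year, founder-population and census-gap
scenarios, and a warden headcount with a mass-dismissal step.

## Worked example

`examples/alarm_bell_detection.py` switches a 20 %/yr removal on right
after a 20-year fit window (changepoint τ = 1943) and asks the model
where the record stops being explainable:

```
fit window (1922, 1942); true changepoint tau = 1943
first band exit: 1944

year  observed  latent(no removal)  inside band
1943      4002          4002        yes
1944      2797          3496        NO  <- alarm
1945      2708          4006        NO  <- alarm
...
across 100 replicate experiments the alarm rings within [tau, tau+3] in 100% of runs
```

The observed census (with removal) and its latent no-intervention twin
agree until τ; one year later the observation has left the 90 % band and
the alarm rings — localizing the onset of the non-ecological cause to
within a year of the truth. The other examples cover plain
fit-and-forecast (`fit_and_forecast.py`), station averaging + proxy R²
and lagged warden–census correlation (`proxy_and_lag_correlations.py`),
and the founder-population regime (`founder_growth.py`).

A thin command line mirrors the library:

```
ibexdyn generate --seed 17 --outdir data/
ibexdyn detect --census data/census.csv --climate data/climate.csv \
    --train-start 1922 --train-end 1938 --n-real 1000 --seed 17 --outdir out/
```

All randomness flows from the single `--seed`; identical configs give
byte-identical outputs.

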