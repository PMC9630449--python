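# firesmoke

Health-burden attribution for vegetation-fire smoke. `firesmoke` estimates
how many hospital visits for respiratory disease are attributable to
fire-originated PM10 in a monitored region, and how that burden changed
around a regulatory burning ban. It is written for air-pollution
epidemiologists and environmental-health analysts who have four routine
data products: hourly PM10 monitor records, satellite fire-hotspot
detections, district population counts, and daily hospital-visit counts by
province and age group.

## The method

**Exposure.** Hourly PM10 is collapsed to station-day means (a day is kept
only with ≥ 18 of 24 valid hours), mapped to districts by nearest monitor,
and population-weighted to a province-day concentration

    PM10_w = Σ_i C_i · P_i / P_tot

with `C_i` the district concentration and `P_i` its population. A
**burning day** is a province-day on which the regional daily hotspot
count (after excluding detections with confidence < 20%) exceeds its 90th
percentile *and* the province's daily PM10 exceeds a cut-point (default
100 μg/m³; the sensitivity analysis lowers it to 50). Days with zero
regional hotspots are **background days**. On background days PM10 is
regressed on a natural cubic spline of time (4–6 df per year, the minimal
adequate model chosen by nested F-tests, AIC reported) plus day-of-week
indicators; the seasonality/DOW-adjusted mean of this model is the
province's scalar background concentration. Fire-originated PM10 on a
burning day is the subtraction estimator

    PM10_fire = max(0, PM10_daily − PM10_background).

**Burden.** A concentration–response function supplies the relative risk
per 10 μg/m³ (defaults: all ages 1.020 [1.012, 1.028]; children < 15
1.009 [1.001, 1.017]; adults ≥ 65 1.021 [1.007, 1.035]). Per province-day,

    RR  = exp(β · PM10_fire),      β = ln(RR_10)/10
    PAF = (RR − 1)/RR
    attributable cases = HV · PAF

with HV the day's visit count. Cases are summed by province, year and age
group; uncertainty ranges re-run the attribution at the CRF's 95% CI
bounds. The before/after ban contrast reports annual means per period
(default 2014–2016 vs 2017–2018).

Because real monitor and health records of this kind are access-restricted,
the package ships a first-class synthetic generator
(`firesmoke.synthetic`) that emulates all four inputs with known ground
truth, calibrated to realistic magnitudes (background ≈ 23 μg/m³, fire
spikes ≈ 107 μg/m³, a dry-season burning calendar thinned after the ban).

## Worked example

```python
from firesmoke import SimScenario, simulate_inputs, run_pipeline

bundle = simulate_inputs(SimScenario(n_provinces=3, seed=11))
result = run_pipeline(bundle.hourly, bundle.hotspots,
                      bundle.population, bundle.visits)
```

Running `python examples/03_estimate_burden.py` (the same computation)
prints:

```
attributable visits (all ages): 7,496 (uncertainty 4,726-9,997)
share of all visits           : 1.5%
share of burning-day visits   : 20.7%
ground-truth expected excess  : 7,123
```

The first line is the estimated number of respiratory hospital visits
attributable to fire-originated PM10 over the five simulated years, with
the range obtained from the CRF's confidence bounds. The estimate sits
within ~5% of the scenario's analytic expected excess (7,123), the
built-in check that the whole chain — completeness filtering, weighting,
classification, background subtraction, attribution — recovers a known
truth. The other `examples/` scripts walk through input simulation, the
exposure decomposition by hand, and the ban/sensitivity contrasts.

A thin CLI wraps the same pipeline for file-based runs:

```bash
firesmoke-burden simulate --seed 11 --provinces 3 --out inputs/
firesmoke-burden run --monitors inputs/monitors_hourly.csv \
    --hotspots inputs/hotspots.csv --population inputs/district_population.csv \
    --visits inputs/hospital_visits.csv --out results/
firesmoke-burden sensitivity --cutoff 50 ...   # config-only rerun
```

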