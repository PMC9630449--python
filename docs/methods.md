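# Methods

## Model and assumptions

The package implements a two-stage attribution. Stage one decomposes a
province's daily PM10 into a background level and a fire-originated
excess; stage two converts that excess into attributable hospital visits
through a log-linear concentration–response function (CRF). The central
assumptions are:

- **Same-day exposure.** The relative risk applies to the same day's
  fire-originated PM10; no lag structure is modelled.
- **Subtraction attribution.** Fire-originated PM10 is the excess of the
  observed daily concentration over a background scalar — there is no
  chemical-transport or source-apportionment modelling. Whatever elevates
  PM10 on a burning day beyond the background (including any seasonal
  elevation not captured by "background", see Limitations) is attributed
  to fire.
- **Scalar background per province.** The background is one number per
  province (the seasonality/day-of-week-adjusted mean over zero-hotspot
  days), not a time-varying curve. The fitted daily curve is kept on the
  model object as a diagnostic but is not used in the subtraction.
- **Multiplicative daily risk.** RR = exp(β·PM10_fire) is applied per
  province-day to that day's visit count, and attributable cases
  HV·(RR−1)/RR are summed. Applying the CRF to period-average exposure
  would understate the burden under Jensen's inequality; the daily
  application is the one consistent with daily visit counts.

## Exposure decomposition

**Daily means.** A station-day mean requires ≥ 18 of 24 valid hourly
values (75% completeness); otherwise the day is missing. Negative and
sentinel (−999/−9999) concentrations are recoded to missing at read time
with a warning — never passed through as numbers.

**District mapping and weighting.** Each district takes the daily value
of its nearest same-province monitor (great-circle distance, ties broken
by station id); the province concentration is the population-weighted
mean Σ C_i·P_i/P_tot. The weighted value is reported only when every
district has a value, so a partly missing day cannot masquerade as a
low-coverage average. When station or district coordinates are absent
from the inputs, every district falls back to the unweighted mean of its
province's stations for that day.

**Burning-day rule.** Daily regional hotspot counts are computed after
excluding detections with confidence < 20% (strict), zero-filled over the
study period. The count threshold is the nearest-rank 90th percentile of
that daily distribution (rank ⌈0.9·n⌉ of the sorted multiset), computed
region-wide across all years; classification uses strict "exceeds". A
province-day is *burning* when the regional count exceeds the threshold
AND the province's weighted PM10 exceeds the cut-point (default
100 μg/m³); *background* when the regional count is zero; *other*
otherwise. "Other" days (some but sub-threshold fire activity, or
supra-threshold days below the concentration cut-point, or candidate days
with missing PM10) enter neither the background fit nor the attribution.
The threshold can be pinned by `hotspot_count_override` in the config.

**Background model.** On a province's background days, PM10 is regressed
by OLS on a natural cubic spline of the day index (knots at quantiles;
total df = df-per-year × study years, rounded) plus day-of-week
indicators. Candidates of 4, 5 and 6 df per year are fitted; the minimal
adequate model is the smallest candidate that no richer candidate
improves at the 0.05 level by nested F-test, with AIC recorded for every
candidate. At least 30 background days with data are required; a design
rank-deficient beyond the expected spline/intercept overlap is an error.

The **background scalar** is the mean residual over the fit days (zero
for OLS, retained for transparency of the definition) plus the mean of
the model's predictions over *every calendar day* of the study period.
Averaging predictions over the full calendar rather than over the
background days themselves is deliberate: background days under-sample
the fire season, and the raw mean over them would be biased by exactly
the seasonal imbalance the spline is there to remove. With this
definition the scalar is invariant to when background days happen to
fall (verified on noiseless seasonal data, where it recovers the
generating mean to ~0.01 μg/m³ under heavy dry-season censoring), and
shifts by exactly c when all observations shift by c.

**Fire-originated PM10** on a burning day is the weighted daily value
minus the background scalar, floored at zero (attributable cases cannot
be negative); clamps and burning days dropped for missing PM10 are
logged.

## Burden estimation

β = ln(RR_10)/10 per age group. Default CRF table (relative risk per
10 μg/m³, with 95% CI): all ages 1.020 (1.012, 1.028); children under 15
1.009 (1.001, 1.017); older adults ≥ 65 1.021 (1.007, 1.035). The
older-adult coefficient originates from chronic lower respiratory
outpatient visits and is applied here to the all-respiratory visit series
— a deliberate caveat carried in this note rather than hidden. Uncertainty
ranges re-run the full attribution with β from the CI bounds; only CRF
uncertainty is propagated, not exposure-model uncertainty.

Aggregates per (province, year, age group): summed attributable cases
with their bounds, the mean daily PAF, the share of all visits and of
burning-day visits (percent), and attributable cases per 100,000
residents using the reference-year province population (zero population
leaves incidence missing, with a warning). Published-style tables round
to 0.1 thousand cases and 0.1%; internal computation is full precision,
and CSV output round-trips bit-exactly (`float_precision="round_trip"`
on read).

## Intervention contrast

Period membership is by calendar year (default before = 2014–2016,
after = 2017–2018; the ban date is kept in the config for documentation
only). Each metric's period value is the unweighted mean of its per-year
values — no day-weighting — and the contrast reports absolute and percent
change. This is a descriptive before/after comparison, not a causal
design.

## Synthetic generator

The generator emulates the study conditions so every stage is testable
without restricted data. Defaults: 8 provinces × 5 years (2014–2018), two
monitors and four districts per province; background 23.2 μg/m³ with a
±2 μg/m³ even spread across provinces; an annual cosine of amplitude
12 μg/m³ peaking in the dry season; day-of-week offsets of ±2 μg/m³; 30
regional fire days per year in January–April, thinned to 35% from the ban
year on (matching the observed ~3× drop in burning days); fire spikes
Normal(106.5, 20) μg/m³ truncated at zero; hotspot counts Poisson(40) on
fire days and Poisson(1.5) otherwise with confidences uniform on [0, 100]
(so the < 20% filter removes about a fifth); hourly noise σ = 5 μg/m³;
2% of station-days given fewer than 18 valid hours. Visit counts are
Poisson with log-rate linear in the true fire PM10 — one shared true
coefficient ln(1.020)/10 across age components — with baselines of
45/14/33 visits per province-day for children, older adults and the
remainder; the all-ages series is their sum, so the reported subgroups
can never exceed it. Counts are drawn by inverting shared uniforms, so a
counterfactual regeneration with fire set to zero is coupled by common
random numbers, which is what makes the estimator-vs-excess oracle
comparison sharp at realistic sizes.

What the generator does **not** emulate: spatial fire spread and
meteorology, transboundary smoke, monitor drift or calibration error,
care-seeking behaviour changes during haze episodes, and age-specific
true coefficients. Passing tests therefore demonstrate that the
implementation recovers the quantities it defines under the stated model,
not that the model captures every feature of real data.

All randomness descends from the scenario seed through named, crc32-keyed
seed streams, so each component is independently reproducible.

## Numerical choices

- Nearest-rank percentile (rank ⌈p·n⌉, 1-based) for the hotspot
  threshold; strict inequalities in both burning criteria.
- Spline design uses patsy's `cr` basis; its span includes the constant,
  so the design carries exactly one redundant dimension, resolved by the
  pseudoinverse; deeper rank deficiency raises.
- Station-assignment ties break lexicographically; sorts are stable
  (mergesort) so outputs are deterministic row-for-row.
- Negative fire PM10 clamps to zero; missing is NaN throughout, never a
  sentinel.
- Test problem sizes: the end-to-end suites use 3-province × 5-year
  scenarios (and 2-province variants for focused checks), the oracle
  comparison uses ~150,000 expected excess events; the acceptance script
  runs the full 8-province × 5-year scenario.

## Limitations

- The scalar background attributes dry-season seasonal elevation on
  burning days to fire: with seasonal amplitude 12 μg/m³ this inflates
  fire PM10 by ~9 μg/m³ on average relative to the injected spike
  (measured on the default scenario). It is the estimand of the
  subtraction design, not an implementation artifact; the recovery tests
  distinguish the two.
- Fire days whose concentration stays below the cut-point are censored
  into "other" (~6% under the default calibration); classifier
  sensitivity ≥ 0.95 is guaranteed only for spikes well above the
  cut-point.
- Hotspot counts are used region-wide; provinces share one burning
  calendar criterion on the count side, differing only through their
  concentration criterion.
- Uncertainty ranges ignore exposure-model and classification
  uncertainty; they reflect the CRF's confidence interval only.
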