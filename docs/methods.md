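# Methods

This note documents the statistical model the package implements, the design
choices that were genuinely open, and what the synthetic-data tests do and do
not establish about real surveillance data.

## The design

During the early COVID-19 pandemic in England, emergency-department (ED)
attendance for suspected cardiac disease fell abruptly while cardiac
mortality rose. The package estimates the causal effect of ED attendance on
cardiac deaths with an *instrumented difference-in-differences* design: the
pandemic-onset indicator

```
z_t = 1{period = current} · 1{date_t ≥ cutoff}
```

(cutoff: March 12, 2020, the date the UK COVID-19 risk level was raised to
high) instruments daily ED visits `x_t`. Identification requires the
exclusion restriction — that pandemic onset affected cardiac deaths only
through reduced attendance, not through, say, stress-induced incidence. The
package documents but cannot test this assumption.

The structural effect is estimated by two-stage least squares on a panel of
daily observations pooling the current period (December 18, 2019 – April 15,
2020) with an averaged historical comparator on the same day-offset axis:

* stage 1: `x_t = π0 + π1 z_t + f(t) + v_t`
* stage 2: `y_{t+L} = β x̂_t + f(t) + u_t`

where `f(t) = γ1·period + γ2 t + γ3 t² + γ4 t³` adjusts for seasonality in
both stages, and `L` is the mortality lag, scanned over 0–20 days because
untreated acute cardiac disease can kill immediately (arrhythmia) or after a
delay (decompensation). `β` is deaths per additional visit; reported effects
are `−100 β`, "excess deaths per 100 non-attendances". In the
just-identified design the 2SLS coefficient equals the Frisch–Waugh ratio
`cov(ỹ, z̃)/cov(x̃, z̃)` (residualising on `[1, f(t)]`); the package keeps
both routes and tests their equivalence to 1e-8.

Derived quantities: the weekly attendance decline is `−7 π̂1` with interval
`±1.96·7·se(π̂1)`; weekly excess deaths are `(per-100 effect) × decline /
100`, with the interval obtained by scaling the effect interval while the
decline is held at its point estimate (the convention that reproduces the
relation between published effect and excess intervals; a delta-method
product-variance alternative is available via
`excess_weekly_deaths(..., method="delta")`, neglecting the covariance
between the two estimates); visits-per-death is `round(100 / per-100
effect)`, half away from zero. A sensitivity analysis refits the design with
the cutoff shifted by −3…+3 days.

## Input preparation

* **Coverage scaling.** Sentinel-network attendance counts (60 of England's
  180 EDs) are multiplied by 3 before analysis (`scale_factor`,
  configurable).
* **Temporal disaggregation.** Weekly death registrations are converted to
  daily values by a mass-preserving linear scheme: within each week the
  seven values lie on a line centred on the weekly mean `c_i/7`, with slope
  `(m_{i+1} − m_{i−1})/14` per day from the neighbouring weekly means
  (one-sided at the edges). Each week's seven values sum exactly to its
  total; a flat series reduces to `c/7`; negative interpolants are clipped
  to zero with the week renormalised and a logged warning. The operator is
  linear (`daily = L·weekly`), which the variance model exploits.
* **Calendar alignment.** Current and historical series are keyed by day
  offset from the window start. If exactly one series lacks February 29 (a
  comparator averaged over non-leap years), the leap day is dropped from the
  other; the synthetic generator instead emits its comparator *with* a
  leap-day value (the expectation evaluated at that date, equivalent to the
  common neighbour-average convention), keeping 120 current-period days and
  avoiding an 8-day registration "week".

## Lag-aligned exposure filtering (pipeline default)

Disaggregation is a smoothing filter applied to the outcome. Regressing a
filtered outcome on an *unfiltered* daily exposure attenuates the IV ratio:
the numerator `cov(z̃, F y)` carries the filter while the denominator
`cov(z̃, x̃)` does not. In noiseless simulation the bias is about −5%
(8.01 recovered for a true 8.4), and the lag-scan maximiser drifts 2–3 days
late, because the smoothing kernel shifts the peak of an asymmetric lag
profile toward its shallow side.

The remedy is standard for temporally aggregated regressions: filter both
sides identically. The pipeline aggregates the (scaled) daily exposure into
7-day bins and linearly disaggregates it with the *same* scheme, with bins
placed so that after the outcome is shifted by the scan lag `L` the two
filters coincide on the panel's time axis (bin starts congruent to `−L mod
7` relative to the outcome's registration weeks). At the true lag the
smeared excess in the outcome is then exactly `β` times the smeared
exposure step, so noiseless recovery is exact (8.38 observed, the residual
0.02 being the cubic-in-t approximation of the annual harmonic), and the
noiseless lag profile peaks at the true lag. The filter can be disabled
(`exposure_filter="none"`); the first-stage weekly-decline estimate always
uses the raw daily exposure, since it quantifies the attendance drop itself.

Filtering cannot restore sub-weekly information the weekly outcome never
carried: the lag profile remains flat within ±2 days of its peak and shows
mild mod-7 scalloping, so single-day lag resolution is not attainable from
weekly registration data — lag estimates should be read as ±2 days.

## Variance estimation

Three estimators for the structural standard error are provided (all use the
proper 2SLS residual, computed with the observed exposure):

* `classical` — homoskedastic `σ̂²(X̂'X̂)⁻¹`. Correct for independent daily
  noise (verified by a 1000-replicate coverage test on iid panels), but far
  too small for disaggregated outcomes: days within a registration week
  share the week's count, and the centred scheme ties days up to ~20 days
  apart. Monte Carlo coverage under the default generator: ~50%.
* `newey_west` — Bartlett-kernel HAC applied within each period's time
  ordering (default bandwidth 21 days, covering the filter's dependence
  span), with an `n/(n−k)` correction. Better, but still undersized here:
  each period contributes only ~17 weekly observations, and in-sample HAC
  at such sizes is well known to underestimate long-run variance (observed
  coverage 66–85% across kernels and bandwidths).
* `count_model` (pipeline default) — a model-based sandwich. The serial
  correlation is induced by our own known linear filter `L`, applied to
  registration counts modelled as Poisson, so the error covariance is
  computable rather than estimable: `Cov(daily) = L diag(V) L'` with `V` the
  observed weekly totals (scaled by the coverage factor for a scaled count,
  since `Var(a·Poisson) = a·value`, and divided by the number of pooled
  years for an averaged comparator). The structural error covariance is the
  outcome part plus `β̂²` times the exposure part, sandwiched between the
  stage-2 projection. Monte Carlo under the default generator: 93% coverage
  at the true effect, 6–7% null size.

The count-model covariance indexes days by calendar offset and therefore
assumes no leap-day was dropped during alignment (true for the generator's
convention); use `newey_west` for a 119-day comparator axis. Intervals use
the normal 1.96 critical value throughout (n ≈ 240 makes the t-correction
negligible). A first-stage strength guard (`|π̂1|/se ≥ 2` by default) raises
a weak-instrument error instead of returning an unstable ratio.

## The synthetic-data generator

`ScenarioParams` defaults define the study conditions the analysis targets:

| parameter | default | rationale |
| --- | --- | --- |
| `baseline_visits` | 1120 /day | ≈7850/week nationally, so a 35% drop gives the ~2750/week decline scale |
| `baseline_deaths` | 185 /day | ≈1290/week non-COVID cardiac deaths, consistent with a ~230/week excess being ~18% |
| `seasonal_amplitude_*` | 0.10 | ~10% winter excess (peak early January) for both attendance and cardiac mortality |
| `trend_coefs_*` | 0 | no secular trend by default; settable to test misspecification |
| `shock_fraction` | 0.35 | ~35% step reduction in attendance from the cutoff |
| `true_beta_per100` | 8.4 | upper-bound effect size; set to 0 for null scenarios |
| `true_lag` | 18 | upper-bound mortality lag |
| `noise` | `poisson` | counts; `none` gives exact expectations |
| `n_historical_years` | 5 | comparator depth |
| `coverage_factor` | 3 | visits emitted at sentinel scale (national/3) |

Expected visits on day *t* are `baseline · (1 + A·cos(2π(doy −
peak)/365.25) + c1 t + c2 t² + c3 t³)`, times `(1 − shock)` from the cutoff
in the current period; expected deaths add `(true_beta_per100/100) ×`
(counterfactual − actual expected visits) displaced by `true_lag` days.
Deaths are emitted as weekly sums (forcing the pipeline through
disaggregation); visits carry a week of padding each side of the window so
weekly filtering has complete bins at every alignment; the historical
comparator averages independently simulated no-shock years; one
pseudo-random stream per series is split from the master seed, so adding a
series never perturbs another. The generator's seasonality is a single
annual harmonic plus cubic trend — deliberately expressible in (but
slightly richer than) the estimator's adjustment basis.

What the generator does **not** emulate: day-of-week attendance cycles,
COVID-19 death misclassification, reporting delays, sentinel-sample
selection bias, overdispersion beyond Poisson, or any violation of the
exclusion restriction. Passing tests therefore show the *procedure* is
correct and calibrated under its own assumptions, not that those assumptions
hold for Public Health England / ONS data.

## Numerical choices and problem sizes

All regressions go through a QR factorisation (the cubic trend makes the
normal equations ill-conditioned); rank deficiency is reported with the
collinear columns identified by pivoted QR. Determinism: identical inputs
and configuration give bit-identical outputs; scenario files are
byte-stable for a fixed seed. Effect tables report one decimal place.

Monte Carlo checks in the test suite use 300 replicates for recovery and
coverage (true lag 10), 300 for null calibration, 1000 for iid-panel
coverage, and 1000 random series for mass conservation; the full suite runs
in about a minute and a half on one CPU.

## Known limitations

* Lag localisation from weekly outcome data is ±2 days at best (above).
* The excess-deaths interval holds the decline fixed; the delta-method
  variant neglects the covariance between decline and effect estimates.
* The historical comparator is a single averaged series; pooling individual
  historical years as separate period-0 rows would change the effective
  weighting (the source material for the design documents only the averaged
  curves).
* Over-identification (multiple instruments) and count-likelihood
  (Poisson/negative-binomial) structural models are out of scope, as are
  cumulative-harm estimates beyond the 20-day horizon.
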