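# ivdid

Instrumented difference-in-differences estimation of the effect of reduced
emergency-department (ED) attendance on cardiac mortality.

During the early COVID-19 pandemic, ED visits for suspected cardiac disease
in England fell by roughly a third within days, while cardiac deaths rose
with a delay. `ivdid` is a tested, reusable pipeline for quantifying how
much of that excess mortality is attributable to the missed attendances. It
is aimed at epidemiologists and health-data scientists working with
surveillance count series: a sentinel-network daily attendance series and
weekly death registrations, each paired with a multi-year historical
comparator.

## Method

The pandemic-onset indicator `z_t = 1{current period, date ≥ cutoff}`
(cutoff: March 12, 2020) serves as an instrument for daily ED visits `x_t`.
Pooling the current period with the historical comparator on a common
day-offset axis, the effect of visits on deaths at mortality lag `L` is
estimated by two-stage least squares,

    stage 1:  x_t     = π₀ + π₁ z_t + f(t) + v_t
    stage 2:  y_{t+L} = β x̂_t + f(t) + u_t,      f(t) = γ₁·period + γ₂t + γ₃t² + γ₄t³,

with `−100·β` reported as excess deaths per 100 non-attendances. The lag is
scanned over 0–20 days. Around the estimator the pipeline handles: scaling
sentinel counts to national coverage (×3), mass-preserving linear
disaggregation of weekly deaths to daily values, lag-aligned weekly
filtering of the exposure (so both regression sides carry the same temporal
filter — see `docs/methods.md`), first-stage estimation of the weekly
attendance decline (`−7π̂₁`), conversion to weekly excess deaths and a
visits-per-death figure, and a ±3-day cutoff sensitivity analysis. Standard
errors default to a model-based variance that propagates Poisson
weekly-count noise through the known disaggregation filter; classical and
Newey–West variants are available.

A synthetic-data generator (`ivdid.synthetic`) produces paired visit/death
series with known ground truth — seasonal Poisson counts, a step reduction
in visits from the cutoff, and a lag-displaced mortality excess — so every
pipeline stage is testable without access to the original surveillance
extracts.

## Worked example

```python
from ivdid import ScenarioParams, generate_scenario, analyze_scenario

params = ScenarioParams(seed=1)            # defaults: 35% visit shock,
scenario = generate_scenario(params)       # 8.4 deaths per 100 at lag 18
result = analyze_scenario(scenario)

scan = result.lag_scan.set_index("lag")
print(f"weekly decline: {result.decline.decline:.0f}")
print(f"per-100 effect, lag 0:  {scan.loc[0, 'beta_per100']:.1f}")
print(f"per-100 effect, lag 18: {scan.loc[18, 'beta_per100']:.1f}")
print(f"visits per excess death: {result.visits_per_death}")
```

prints

```
weekly decline: 2870
per-100 effect, lag 0:  2.7
per-100 effect, lag 18: 8.1
visits per excess death: 12
```

Read: attendance fell by ~2870 visits/week at the cutoff; each 100 missed
visits were followed by 8.1 (95% CI 6.4–9.7) excess cardiac deaths at an
18-day lag (the generator's truth is 8.4 at lag 18 — the lag-0 estimate is
small because most of the injected excess has not yet occurred); about one
death per 12 missed visits. The corresponding weekly excess at lag 18 is
231 deaths (95% CI 184–279).

The same analysis runs from the shell:

```sh
ivdid simulate --seed 1 --out scenario/
ivdid analyze --scenario scenario/ --out results/
# results/: lag_scan.csv, excess.csv, sensitivity.csv, report.txt
```

For real data, pass the four CSV series (daily `date,value[,interpolated]`,
weekly `date,count`) plus `--window-start/--window-end/--cutoff` instead of
`--scenario`.

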