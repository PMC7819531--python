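"""Synthetic paired ED-visit and cardiac-death series with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* multi-year seasonal daily counts (annual harmonic plus optional cubic
  trend) with Poisson noise;
* a step reduction in ED visits from the pandemic cutoff date;
* a lag-distributed increase in cardiac deaths proportional to the visits
  forgone, with a known per-100 effect size and a known lag;
* visits observed at sentinel-network scale (national expectation divided by
  a coverage factor) so the pipeline exercises the coverage scaling;
* deaths emitted as weekly registration totals, forcing the pipeline through
  temporal disaggregation;
* a historical comparator built by averaging independently simulated
  no-shock years.

Every generated scenario carries a truth record with the generator internals
(true effect, true lag, expected weekly decline, total forgone visits and
injected excess deaths) so recovery can be checked against ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeseries import (
    DailySeries,
    StudyWindow,
    WeeklySeries,
    default_study_window,
    read_count_series,
)

#: day of year at which winter seasonality peaks (early January)
SEASONAL_PEAK_DOY = 10

#: days of outcome data generated beyond the window end, covering lagged
#: outcomes for the full 0-20 day scan
OUTCOME_EXTENSION_DAYS = 28


@dataclass(frozen=True)
class ScenarioParams:
    """Complete parameterisation of the synthetic data-generating process.

    Defaults reflect the English setting the analysis targets: a national
    baseline of ~1120 daily ED visits for suspected cardiac disease (so a 35%
    step reduction gives a weekly decline near 2750), ~185 daily cardiac
    deaths, a 10% winter-peaking seasonal amplitude on both series, a true
    effect of 8.4 excess deaths per 100 forgone visits at an 18-day lag, and
    a sentinel network covering one third of EDs.
    """

    baseline_visits: float = 1120.0
    baseline_deaths: float = 185.0
    seasonal_amplitude_visits: float = 0.10
    seasonal_amplitude_deaths: float = 0.10
    trend_coefs_visits: tuple = (0.0, 0.0, 0.0)
    trend_coefs_deaths: tuple = (0.0, 0.0, 0.0)
    shock_fraction: float = 0.35
    true_beta_per100: float = 8.4
    true_lag: int = 18
    noise: str = "poisson"
    n_historical_years: int = 5
    coverage_factor: float = 3.0
    window: StudyWindow = field(default_factory=default_study_window)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shock_fraction < 1.0):
            raise ValidationError(
                f"shock_fraction must be in [0, 1), got {self.shock_fraction}"
            )
        for name in ("seasonal_amplitude_visits", "seasonal_amplitude_deaths"):
            a = getattr(self, name)
            if not (0.0 <= a < 1.0):
                raise ValidationError(f"{name} must be in [0, 1), got {a}")
        if not (0 <= int(self.true_lag) <= 20):
            raise ValidationError(f"true_lag must be in [0, 20], got {self.true_lag}")
        if self.noise not in ("poisson", "none"):
            raise ValidationError(f"noise must be 'poisson' or 'none', got {self.noise!r}")
        if self.baseline_visits <= 0 or self.baseline_deaths <= 0:
            raise ValidationError("baselines must be positive")
        if int(self.n_historical_years) < 1:
            raise ValidationError("n_historical_years must be >= 1")
        if not self.coverage_factor >= 1.0:
            raise ValidationError("coverage_factor must be >= 1")
        object.__setattr__(self, "true_lag", int(self.true_lag))
        object.__setattr__(self, "n_historical_years", int(self.n_historical_years))
        object.__setattr__(self, "trend_coefs_visits", tuple(self.trend_coefs_visits))
        object.__setattr__(self, "trend_coefs_deaths", tuple(self.trend_coefs_deaths))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = {
            "window_start": self.window.window_start.strftime("%Y-%m-%d"),
            "window_end": self.window.window_end.strftime("%Y-%m-%d"),
            "cutoff": self.window.cutoff.strftime("%Y-%m-%d"),
            "n_historical_years": self.window.n_historical_years,
        }
        d["trend_coefs_visits"] = list(self.trend_coefs_visits)
        d["trend_coefs_deaths"] = list(self.trend_coefs_deaths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        d = dict(d)
        w = d["window"]
        d["window"] = StudyWindow(
            w["window_start"], w["window_end"], w["cutoff"],
            w.get("n_historical_years", 5),
        )
        d["trend_coefs_visits"] = tuple(d["trend_coefs_visits"])
        d["trend_coefs_deaths"] = tuple(d["trend_coefs_deaths"])
        return cls(**d)


@dataclass(frozen=True)
class Scenario:
    """Generated series plus the ground-truth record."""

    visits_current: DailySeries
    visits_historical: DailySeries
    deaths_current: WeeklySeries
    deaths_historical: WeeklySeries
    truth: dict


def _seasonal_trend(dates: pd.DatetimeIndex, t: np.ndarray, amplitude: float,
                    trend_coefs: tuple) -> np.ndarray:
    """1 + harmonic + cubic-trend multiplier, evaluated per day."""
    doy = dates.dayofyear.to_numpy(float)
    harmonic = amplitude * np.cos(2.0 * np.pi * (doy - SEASONAL_PEAK_DOY) / 365.25)
    c1, c2, c3 = trend_coefs
    return 1.0 + harmonic + c1 * t + c2 * t**2 + c3 * t**3


def expected_visits(params: ScenarioParams, dates: pd.DatetimeIndex,
                    shocked: bool) -> np.ndarray:
    """Expected national daily visits; the shock applies from the cutoff date."""
    t = (dates - params.window.window_start).days.to_numpy(float)
    mu = params.baseline_visits * _seasonal_trend(
        dates, t, params.seasonal_amplitude_visits, params.trend_coefs_visits
    )
    if shocked:
        mu = mu * np.where(dates >= params.window.cutoff,
                           1.0 - params.shock_fraction, 1.0)
    return mu


def expected_deaths(params: ScenarioParams, dates: pd.DatetimeIndex,
                    shocked: bool) -> np.ndarray:
    """Expected national daily deaths, with the lagged excess when shocked.

    The excess on day d is (true_beta_per100 / 100) x visits forgone on day
    d - true_lag, where forgone visits are the counterfactual-minus-actual
    expected attendance.
    """
    t = (dates - params.window.window_start).days.to_numpy(float)
    mu = params.baseline_deaths * _seasonal_trend(
        dates, t, params.seasonal_amplitude_deaths, params.trend_coefs_deaths
    )
    if shocked:
        source = dates - pd.Timedelta(days=params.true_lag)
        forgone = params.shock_fraction * expected_visits(
            params, pd.DatetimeIndex(source), shocked=False
        ) * (source >= params.window.cutoff)
        mu = mu + (params.true_beta_per100 / 100.0) * forgone
    return mu


def _draw_daily(rng: np.random.Generator, mu: np.ndarray, noise: str) -> np.ndarray:
    return rng.poisson(mu).astype(float) if noise == "poisson" else mu.copy()


def _weekly_sums(values: np.ndarray) -> np.ndarray:
    return values.reshape(-1, 7).sum(axis=1)


def generate_scenario(params: ScenarioParams) -> Scenario:
    """Generate the four input series and the ground-truth record.

    Visits cover the study window with a week of padding on either side (so
    weekly filtering of the exposure has complete bins at every alignment);
    deaths cover the window plus ``OUTCOME_EXTENSION_DAYS`` (rounded up to
    whole weeks) so that lagged outcomes exist for the full lag scan, and are
    emitted as weekly totals.
    The historical comparator is the average of ``n_historical_years``
    independently simulated no-shock years, dated on the current-period
    calendar (a leap day, when present, takes its own expected value — the
    month-day-axis convention for multi-year averages).
    """
    w = params.window
    n_death_days = 7 * -(-(w.n_days + OUTCOME_EXTENSION_DAYS) // 7)
    death_dates = pd.date_range(w.window_start, periods=n_death_days, freq="D")
    # a week of padding on each side so lag-aligned weekly filtering of the
    # exposure covers the full window at every bin alignment
    visit_dates = pd.date_range(
        w.window_start - pd.Timedelta(days=7), periods=7 + n_death_days, freq="D"
    )

    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(params.seed).spawn(4)
    ]
    rng_vc, rng_vh, rng_dc, rng_dh = streams

    # current period, sentinel scale for visits
    mu_vc = expected_visits(params, visit_dates, shocked=True)
    visits_current = DailySeries(
        visit_dates,
        _draw_daily(rng_vc, mu_vc / params.coverage_factor, params.noise),
        label="visits_current",
    )

    mu_dc = expected_deaths(params, death_dates, shocked=True)
    if params.noise == "poisson":
        deaths_current_weekly = rng_dc.poisson(_weekly_sums(mu_dc)).astype(float)
    else:
        deaths_current_weekly = _weekly_sums(mu_dc)
    deaths_current = WeeklySeries(
        pd.DatetimeIndex(death_dates[::7]), deaths_current_weekly,
        label="deaths_current",
    )

    # historical comparator: average of independent no-shock years
    mu_vh = expected_visits(params, visit_dates, shocked=False)
    mu_dh = expected_deaths(params, death_dates, shocked=False)
    k = params.n_historical_years
    if params.noise == "poisson":
        vh = rng_vh.poisson(
            np.broadcast_to(mu_vh / params.coverage_factor, (k, len(mu_vh)))
        ).mean(axis=0)
        dh = rng_dh.poisson(
            np.broadcast_to(_weekly_sums(mu_dh), (k, len(mu_dh) // 7))
        ).mean(axis=0)
    else:
        vh = mu_vh / params.coverage_factor
        dh = _weekly_sums(mu_dh)
    visits_historical = DailySeries(visit_dates, vh, label="visits_historical")
    deaths_historical = WeeklySeries(
        pd.DatetimeIndex(death_dates[::7]), dh, label="deaths_historical"
    )

    post_dates = pd.date_range(w.cutoff, w.window_end, freq="D")
    forgone_window = params.shock_fraction * expected_visits(
        params, post_dates, shocked=False
    )
    truth = {
        "params": params.to_dict(),
        "true_beta_per100": params.true_beta_per100,
        "true_lag": params.true_lag,
        "coverage_factor": params.coverage_factor,
        "expected_weekly_decline": 7.0 * float(forgone_window.mean()),
        "total_forgone_visits": float(forgone_window.sum()),
        "total_excess_deaths": params.true_beta_per100 / 100.0
        * float(forgone_window.sum()),
    }
    return Scenario(
        visits_current=visits_current,
        visits_historical=visits_historical,
        deaths_current=deaths_current,
        deaths_historical=deaths_historical,
        truth=truth,
    )


_FILES = {
    "visits_current": ("visits_current.csv", "daily"),
    "visits_historical": ("visits_historical.csv", "daily"),
    "deaths_current": ("deaths_current.csv", "weekly"),
    "deaths_historical": ("deaths_historical.csv", "weekly"),
}


def write_scenario(scenario: Scenario, directory) -> list[Path]:
    """Write the four series CSVs plus truth.json; byte-stable for a fixed seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, (fname, _) in _FILES.items():
        path = directory / fname
        getattr(scenario, attr).to_frame().to_csv(path, index=False)
        written.append(path)
    truth_path = directory / "truth.json"
    truth_path.write_text(
        json.dumps(scenario.truth, indent=2, sort_keys=True) + "\n"
    )
    written.append(truth_path)
    return written


def read_scenario(directory) -> Scenario:
    """Read back a scenario directory written by :func:`write_scenario`."""
    directory = Path(directory)
    series = {
        attr: read_count_series(directory / fname, freq)
        for attr, (fname, freq) in _FILES.items()
    }
    truth = json.loads((directory / "truth.json").read_text())
    return Scenario(truth=truth, **series)
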