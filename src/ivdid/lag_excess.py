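"""Lag scan, excess-mortality conversion, and cutoff sensitivity analysis.

Acute cardiac disease left untreated can kill immediately (arrhythmia) or
after a delay (progressive heart failure), so the exposure-outcome lag is
unknown a priori. The scan refits the 2SLS design with the outcome shifted by
each lag from 0 to ``max_lag`` days. Per-lag effects are then converted into
policy-facing quantities: the weekly decline in attendance implied by the
first stage, excess deaths per week, and the number of forgone visits per
excess death.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError, WeakInstrumentError
from .estimator import Z_95, IVEstimate, ols_solve, tsls_fit
from .panel import COVARIATES, build_panel
from .timeseries import StudyWindow

_SCAN_COLUMNS = [
    "lag", "beta", "se", "beta_per100", "ci_low", "ci_high", "n_obs", "status"
]


def scan_lags(
    visits: pd.DataFrame,
    deaths: pd.DataFrame,
    window: StudyWindow,
    max_lag: int = 20,
    panel_builder=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the design at every lag 0..max_lag.

    Returns one row per lag with the per-100 effect and its 95% interval
    (``ci_low``/``ci_high`` are on the per-100 scale). A weak-instrument
    failure at one lag is recorded in its ``status`` column without aborting
    the rest of the scan.

    ``panel_builder(lag, window)``, when given, replaces the default
    :func:`build_panel` call and returns ``(panel, extra_fit_kwargs)`` — the
    pipeline uses it for lag-aligned exposure filtering and model-based
    error covariances.
    """
    if max_lag < 0:
        raise ValidationError(f"max_lag must be non-negative, got {max_lag}")
    rows = []
    for lag in range(int(max_lag) + 1):
        if panel_builder is not None:
            panel, extra = panel_builder(lag, window)
        else:
            panel, extra = build_panel(visits, deaths, window, lag), {}
        try:
            est = tsls_fit(panel, **{**fit_kwargs, **extra})
            rows.append(
                {
                    "lag": lag,
                    "beta": est.beta,
                    "se": est.se,
                    "beta_per100": est.beta_per100,
                    "ci_low": est.per100_ci_low,
                    "ci_high": est.per100_ci_high,
                    "n_obs": est.n_obs,
                    "status": "ok",
                }
            )
        except WeakInstrumentError as exc:
            rows.append(
                {
                    "lag": lag,
                    "beta": np.nan,
                    "se": np.nan,
                    "beta_per100": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_obs": len(panel),
                    "status": f"weak_instrument: {exc}",
                }
            )
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


@dataclass(frozen=True)
class WeeklyDecline:
    """First-stage step in attendance, scaled from daily to weekly visits."""

    decline: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.decline <= self.ci_high):
            raise ValidationError("interval does not bracket the estimate")


def estimate_weekly_decline(panel: pd.DataFrame) -> WeeklyDecline:
    """Weekly visit decline from the first-stage instrument coefficient.

    The first stage estimates the daily drop in attendance at the cutoff;
    the weekly decline is -7 x that coefficient, with the interval scaled
    accordingly (se x 7 x 1.96).
    """
    ones = np.ones((len(panel), 1))
    z = panel["z"].to_numpy(float)
    W = np.column_stack([panel[c].to_numpy(float) for c in COVARIATES])
    X1 = np.hstack([ones, z[:, None], W])
    fit = ols_solve(X1, panel["x"].to_numpy(float), ["const", "z", *COVARIATES])
    daily = float(fit.coef[1])
    se_daily = float(np.sqrt(fit.cov[1, 1]))
    decline = -7.0 * daily
    half = Z_95 * 7.0 * se_daily
    return WeeklyDecline(
        decline=decline, se=7.0 * se_daily,
        ci_low=decline - half, ci_high=decline + half,
    )


@dataclass(frozen=True)
class ExcessDeaths:
    """Excess cardiac deaths per week attributable to non-attendance."""

    point: float
    ci_low: float
    ci_high: float
    method: str = "fixed_decline"


def excess_weekly_deaths(
    beta_per100: float,
    per100_ci_low: float,
    per100_ci_high: float,
    weekly_decline: float,
    decline_se: float | None = None,
    method: str = "fixed_decline",
) -> ExcessDeaths:
    """Convert a per-100 effect into excess deaths per week.

    point = beta_per100 x decline / 100. With ``method="fixed_decline"``
    (default) the interval bounds are the per-100 interval bounds scaled the
    same way, holding the decline at its point estimate. The
    ``"delta"`` method instead propagates both uncertainties by the
    delta-method product variance (requires ``decline_se``; the covariance
    between the two estimates is neglected).
    """
    if not weekly_decline > 0:
        raise ValidationError(
            f"weekly decline must be positive, got {weekly_decline}"
        )
    point = beta_per100 * weekly_decline / 100.0
    if method == "fixed_decline":
        lo = per100_ci_low * weekly_decline / 100.0
        hi = per100_ci_high * weekly_decline / 100.0
    elif method == "delta":
        if decline_se is None:
            raise ValidationError("delta method requires decline_se")
        se_b = (per100_ci_high - per100_ci_low) / (2.0 * Z_95)
        var = (weekly_decline / 100.0) ** 2 * se_b**2 + (
            beta_per100 / 100.0
        ) ** 2 * decline_se**2
        half = Z_95 * math.sqrt(var)
        lo, hi = point - half, point + half
    else:
        raise ValidationError(f"unknown interval method {method!r}")
    return ExcessDeaths(point=point, ci_low=lo, ci_high=hi, method=method)


def visits_per_death(beta_per100: float) -> int:
    """Forgone ED visits per excess cardiac death: round(100 / beta_per100).

    Rounding is half-away-from-zero, so 8.4 per 100 gives 12 visits per death.
    """
    if not beta_per100 > 0:
        raise ValidationError(
            f"beta_per100 must be positive, got {beta_per100}"
        )
    return int(math.floor(100.0 / beta_per100 + 0.5))


def sensitivity_shift_cutoff(
    visits: pd.DataFrame,
    deaths: pd.DataFrame,
    window: StudyWindow,
    offsets=range(-3, 4),
    lag: int = 0,
    panel_builder=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the design with the pandemic cutoff shifted by each offset in days.

    Offset 0 reproduces the main analysis exactly. A shifted cutoff falling
    outside the window raises :class:`ValidationError`.
    """
    rows = []
    for off in offsets:
        shifted = window.cutoff + pd.Timedelta(days=int(off))
        if not (window.window_start < shifted < window.window_end):
            raise ValidationError(
                f"offset {off} moves the cutoff to {shifted.date()}, "
                f"outside the study window"
            )
        w = StudyWindow(
            window.window_start, window.window_end, shifted,
            window.n_historical_years,
        )
        if panel_builder is not None:
            panel, extra = panel_builder(lag, w)
        else:
            panel, extra = build_panel(visits, deaths, w, lag), {}
        try:
            est: IVEstimate = tsls_fit(panel, **{**fit_kwargs, **extra})
            rows.append(
                {
                    "offset": int(off),
                    "cutoff": shifted.strftime("%Y-%m-%d"),
                    "beta_per100": est.beta_per100,
                    "ci_low": est.per100_ci_low,
                    "ci_high": est.per100_ci_high,
                    "n_obs": est.n_obs,
                    "status": "ok",
                }
            )
        except WeakInstrumentError as exc:
            rows.append(
                {
                    "offset": int(off),
                    "cutoff": shifted.strftime("%Y-%m-%d"),
                    "beta_per100": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_obs": len(panel),
                    "status": f"weak_instrument: {exc}",
                }
            )
    return pd.DataFrame(rows)
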