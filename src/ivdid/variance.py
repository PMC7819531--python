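"""Model-based variance for 2SLS on disaggregated count series.

Daily values obtained by disaggregating weekly registration totals are not
independent: every day in a week shares that week's count, and the centred
linear-trend scheme also borrows the neighbouring weeks' totals, so daily
errors are correlated up to about 20 days apart. Sample-based corrections
(Newey-West and kin) are badly downward-biased here because each period
contributes only ~17 weekly observations. But the dependence is induced by a
*known* linear filter applied to counts that the registration model treats
as Poisson — so the error covariance can be computed directly:

    Cov(daily) = L diag(Var(weekly)) L',   Var(weekly) ~= observed total,

with L the disaggregation operator, the variance divided by the number of
pooled years for an averaged historical comparator, and multiplied by the
coverage scale factor for a sentinel series scaled by it (a scaled Poisson
count has variance scale x value). The structural-residual covariance is the
outcome part plus beta^2 times the exposure part (the series are
independent), which the estimator sandwiches between the stage-2 projection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import StudyWindow, WeeklySeries, disaggregation_matrix


@dataclass(frozen=True)
class SeriesCovariance:
    """Daily-value covariance of one disaggregated weekly count series."""

    first_date: pd.Timestamp
    cov: np.ndarray  # (7n, 7n)

    def block(self, day_index: np.ndarray) -> np.ndarray:
        return self.cov[np.ix_(day_index, day_index)]


def weekly_count_covariance(
    weekly: WeeklySeries,
    scale: float = 1.0,
    n_years: int = 1,
) -> SeriesCovariance:
    """Covariance of the daily series disaggregated from ``weekly``.

    ``scale`` is the coverage multiplier already applied to the counts (a
    scaled Poisson has variance scale x observed value); ``n_years`` divides
    the variance for a comparator averaged over that many independent years.
    """
    L = disaggregation_matrix(len(weekly))
    var_weekly = np.maximum(weekly.count, 0.0) * float(scale) / int(n_years)
    cov = (L * var_weekly[None, :]) @ L.T
    return SeriesCovariance(first_date=weekly.week_start[0], cov=cov)


@dataclass(frozen=True)
class CountModelCovariance:
    """Per-panel error covariances for the count-model standard errors.

    Holds the outcome (deaths) covariance per period and, per lag, the
    exposure (visits) covariance per period — the exposure filter bins move
    with the lag, so its covariance does too.
    """

    deaths_current: SeriesCovariance
    deaths_historical: SeriesCovariance
    visits_current: dict  # lag -> SeriesCovariance
    visits_historical: dict
    window: StudyWindow

    def panel_covariances(
        self, panel: pd.DataFrame, lag: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(Sy, Sx): outcome and exposure error covariances on panel rows."""
        n = len(panel)
        Sy = np.zeros((n, n))
        Sx = np.zeros((n, n))
        dates = pd.DatetimeIndex(panel["date"])
        period = panel["period"].to_numpy(int)
        vc = self.visits_current[lag]
        vh = self.visits_historical[lag]
        for p, dcov, vcov in ((1, self.deaths_current, vc),
                              (0, self.deaths_historical, vh)):
            rows = np.nonzero(period == p)[0]
            if not rows.size:
                continue
            d = dates[rows]
            y_idx = (d - dcov.first_date).days.to_numpy() + lag
            x_idx = (d - vcov.first_date).days.to_numpy()
            Sy[np.ix_(rows, rows)] = dcov.cov[np.ix_(y_idx, y_idx)]
            Sx[np.ix_(rows, rows)] = vcov.cov[np.ix_(x_idx, x_idx)]
        return Sy, Sx
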