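"""Assemble the regression-ready analysis panel.

Each panel row pairs the exposure (daily ED visits, scaled to national
coverage) on day ``t`` with the outcome (daily cardiac deaths) on day
``t + lag``, for both the current period and the pooled historical
comparator, together with the instrument and the four seasonality-adjustment
covariates: the period indicator and the linear, squared and cubic day
offsets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeseries import StudyWindow

#: covariates adjusting for seasonality in both 2SLS stages
COVARIATES = ("period", "t", "t2", "t3")

PANEL_COLUMNS = ("date", "period", "t", "t2", "t3", "z", "x", "y")


def build_panel(
    visits: pd.DataFrame,
    deaths: pd.DataFrame,
    window: StudyWindow,
    lag: int,
) -> pd.DataFrame:
    """Build the analysis panel at a given mortality lag.

    Parameters
    ----------
    visits, deaths
        Aligned tables from :func:`ivdid.timeseries.align_calendar`, with
        columns ``offset, date, current, historical``. Both must share the
        window's day-offset origin; the deaths table may (and for positive
        lags must) extend beyond the visits table, else trailing rows whose
        lagged outcome falls outside the data are dropped and counted in
        ``panel.attrs["n_dropped"]``.
    window
        Defines the instrument cutoff: ``z = 1`` exactly for current-period
        rows on or after the cutoff date.
    lag
        Days between a (non-)attendance and the death it is paired with.

    Returns a frame with columns ``date, period, t, t2, t3, z, x, y``,
    historical rows first, ordered by ``t`` within period.
    """
    lag = int(lag)
    if lag < 0:
        raise ValidationError(f"lag must be non-negative, got {lag}")
    if lag > len(visits) - 1:
        raise ValidationError(
            f"lag {lag} exceeds the study window ({len(visits)} days)"
        )

    death_at = {
        int(o): (float(c), float(h))
        for o, c, h in zip(deaths["offset"], deaths["current"], deaths["historical"])
    }

    frames = []
    n_dropped = 0
    for period, x_col in ((0, "historical"), (1, "current")):
        t = visits["offset"].to_numpy(int)
        x = visits[x_col].to_numpy(float)
        y = np.full(len(t), np.nan)
        for i, o in enumerate(t):
            pair = death_at.get(o + lag)
            if pair is not None:
                y[i] = pair[1] if period == 0 else pair[0]
        keep = ~np.isnan(y)
        n_dropped += int((~keep).sum())
        dates = pd.DatetimeIndex(visits["date"])[keep]
        tk = t[keep]
        z = (
            ((dates >= window.cutoff).astype(int))
            if period == 1
            else np.zeros(keep.sum(), int)
        )
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "period": period,
                    "t": tk,
                    "t2": tk**2,
                    "t3": tk**3,
                    "z": z,
                    "x": x[keep],
                    "y": y[keep],
                }
            )
        )

    panel = pd.concat(frames, ignore_index=True)
    if panel.empty:
        raise ValidationError(f"lag {lag} leaves no usable rows")
    panel.attrs["lag"] = lag
    panel.attrs["n_dropped"] = n_dropped
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    """Export a panel as CSV with header ``date,period,t,z,x,y_lagged``."""
    out = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(panel["date"]).strftime("%Y-%m-%d"),
            "period": panel["period"],
            "t": panel["t"],
            "z": panel["z"],
            "x": panel["x"],
            "y_lagged": panel["y"],
        }
    )
    out.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a panel written by :func:`write_panel`, recomputing t powers."""
    raw = pd.read_csv(path)
    required = {"date", "period", "t", "z", "x", "y_lagged"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"panel file missing columns: {sorted(missing)}")
    t = raw["t"].to_numpy(int)
    return pd.DataFrame(
        {
            "date": pd.to_datetime(raw["date"]),
            "period": raw["period"].astype(int),
            "t": t,
            "t2": t**2,
            "t3": t**3,
            "z": raw["z"].astype(int),
            "x": raw["x"].astype(float),
            "y": raw["y_lagged"].astype(float),
        }
    )
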