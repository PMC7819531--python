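"""Count time series: reading, validation, disaggregation, scaling, alignment.

The analysis works with two kinds of series: weekly death registrations
(``WeeklySeries``) and daily attendance or death counts (``DailySeries``).
Weekly mortality counts are disaggregated to daily values under a
mass-preserving linear-trend assumption; sentinel-network attendance counts
are scaled up by a coverage factor; and current-period and historical
comparator series are aligned on a common day-offset axis over the study
window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError

log = logging.getLogger(__name__)

_DAY = pd.Timedelta(days=1)


def _coerce_dates(values, what: str) -> pd.DatetimeIndex:
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(values, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{what}: unparseable ISO-8601 date ({exc})") from exc
    return idx.normalize()


def _is_feb29(dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates.month == 2) & (dates.day == 29)


@dataclass(frozen=True)
class WeeklySeries:
    """Dated weekly counts from a registration source.

    ``week_start`` values must be exactly 7 days apart and strictly
    increasing; counts must be non-negative (real-valued: disaggregated or
    averaged comparators need not be integers).
    """

    week_start: pd.DatetimeIndex
    count: np.ndarray
    label: str = ""

    def __post_init__(self):
        dates = _coerce_dates(self.week_start, f"WeeklySeries({self.label!r})")
        count = np.asarray(self.count, dtype=float)
        if count.ndim != 1 or len(count) != len(dates):
            raise ValidationError("week_start and count must be 1-d and equal length")
        if len(dates) == 0:
            raise ValidationError("empty weekly series")
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        bad = np.nonzero(gaps != 7)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"weekly dates must be exactly 7 days apart; rows {i}-{i + 1} "
                f"({dates[i].date()} -> {dates[i + 1].date()}) are {gaps[i]} days apart"
            )
        if not np.all(np.isfinite(count)):
            i = int(np.nonzero(~np.isfinite(count))[0][0])
            raise ValidationError(f"non-numeric count in row {i} ({dates[i].date()})")
        if np.any(count < 0):
            i = int(np.nonzero(count < 0)[0][0])
            raise ValidationError(
                f"negative count {count[i]} in row {i} ({dates[i].date()})"
            )
        object.__setattr__(self, "week_start", dates)
        object.__setattr__(self, "count", count)

    def __len__(self) -> int:
        return len(self.count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.week_start.strftime("%Y-%m-%d"), "count": self.count}
        )


@dataclass(frozen=True)
class DailySeries:
    """Dated daily values, observed or derived from weekly data.

    Dates must be consecutive; the single permitted gap is an absent
    February 29, so that multi-year averaged comparators built on a 365-day
    month-day axis remain valid instances. ``interpolated`` flags values that
    were derived from weekly data rather than observed.
    """

    date: pd.DatetimeIndex
    value: np.ndarray
    interpolated: np.ndarray | bool = False
    label: str = ""

    def __post_init__(self):
        dates = _coerce_dates(self.date, f"DailySeries({self.label!r})")
        value = np.asarray(self.value, dtype=float)
        if value.ndim != 1 or len(value) != len(dates):
            raise ValidationError("date and value must be 1-d and equal length")
        if len(dates) == 0:
            raise ValidationError("empty daily series")
        interp = self.interpolated
        if np.isscalar(interp):
            interp = np.full(len(dates), bool(interp))
        interp = np.asarray(interp, dtype=bool)
        if len(interp) != len(dates):
            raise ValidationError("interpolated flags must match series length")
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        for i in np.nonzero(gaps != 1)[0]:
            skipped = dates[i] + _DAY
            if gaps[i] == 2 and skipped.month == 2 and skipped.day == 29:
                continue  # comparator axis without a leap day
            raise ValidationError(
                f"daily dates must be consecutive; rows {i}-{i + 1} "
                f"({dates[i].date()} -> {dates[i + 1].date()}) leave a gap"
            )
        if not np.all(np.isfinite(value)):
            i = int(np.nonzero(~np.isfinite(value))[0][0])
            raise ValidationError(f"non-numeric value in row {i} ({dates[i].date()})")
        if np.any(value < 0):
            i = int(np.nonzero(value < 0)[0][0])
            raise ValidationError(
                f"negative value {value[i]} in row {i} ({dates[i].date()})"
            )
        object.__setattr__(self, "date", dates)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "interpolated", interp)

    def __len__(self) -> int:
        return len(self.value)

    def between(self, start, end) -> "DailySeries":
        """Restrict to dates in [start, end] (inclusive)."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        mask = (self.date >= start) & (self.date <= end)
        return DailySeries(
            self.date[mask], self.value[mask], self.interpolated[mask], self.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.date.strftime("%Y-%m-%d"),
                "value": self.value,
                "interpolated": np.where(self.interpolated, "true", "false"),
            }
        )


@dataclass(frozen=True)
class StudyWindow:
    """The study calendar: analysis window, instrument cutoff, comparator depth.

    The cutoff date splits the current period into pre- and post-pandemic
    segments and defines the instrument; it must lie strictly inside the
    window.
    """

    window_start: pd.Timestamp
    window_end: pd.Timestamp
    cutoff: pd.Timestamp
    n_historical_years: int = 5

    def __post_init__(self):
        for name in ("window_start", "window_end", "cutoff"):
            object.__setattr__(self, name, pd.Timestamp(getattr(self, name)).normalize())
        if not (self.window_start < self.cutoff < self.window_end):
            raise ValidationError(
                f"need window_start < cutoff < window_end, got "
                f"{self.window_start.date()} / {self.cutoff.date()} / "
                f"{self.window_end.date()}"
            )
        if int(self.n_historical_years) < 1:
            raise ValidationError("n_historical_years must be a positive integer")
        object.__setattr__(self, "n_historical_years", int(self.n_historical_years))

    @property
    def n_days(self) -> int:
        """Calendar days in the window, endpoints inclusive."""
        return (self.window_end - self.window_start).days + 1

    def extended(self, days: int) -> "StudyWindow":
        """Same window with the end pushed ``days`` later (for lagged outcomes)."""
        return replace(self, window_end=self.window_end + pd.Timedelta(days=days))


def default_study_window() -> StudyWindow:
    """December 18, 2019 - April 15, 2020 with the March 12 pandemic cutoff."""
    return StudyWindow("2019-12-18", "2020-04-15", "2020-03-12")


def read_count_series(path, frequency: str) -> WeeklySeries | DailySeries:
    """Read a validated count series from CSV.

    Weekly files carry columns ``date,count``; daily files carry
    ``date,value[,interpolated]`` (``date,count`` is accepted for daily files
    too). Dates must be ISO-8601. Violations of the series invariants raise
    :class:`ValidationError` naming the offending row.
    """
    if frequency not in ("daily", "weekly"):
        raise ValidationError(f"frequency must be 'daily' or 'weekly', got {frequency!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "date" not in frame.columns:
        raise ValidationError(f"{path.name}: missing 'date' column")
    value_col = "count" if frequency == "weekly" else "value"
    if value_col not in frame.columns:
        if frequency == "daily" and "count" in frame.columns:
            value_col = "count"
        else:
            raise ValidationError(f"{path.name}: missing '{value_col}' column")
    dates = _coerce_dates(frame["date"], path.name)
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate date {dup.date()}")
    values = pd.to_numeric(frame[value_col], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(values)):
        i = int(np.nonzero(~np.isfinite(values))[0][0])
        raise ValidationError(
            f"{path.name}: non-numeric {value_col} {frame[value_col].iloc[i]!r} "
            f"in row {i + 1}"
        )
    order = np.argsort(dates.values, kind="stable")
    dates, values = dates[order], values[order]
    label = path.stem
    if frequency == "weekly":
        return WeeklySeries(dates, values, label=label)
    interp: np.ndarray | bool = False
    if "interpolated" in frame.columns:
        raw = frame["interpolated"].iloc[order].astype(str).str.strip().str.lower()
        interp = raw.isin(("true", "1", "yes")).to_numpy()
    return DailySeries(dates, values, interpolated=interp, label=label)


def disaggregate_weekly_to_daily(weekly: WeeklySeries) -> DailySeries:
    """Estimate daily values from weekly totals under a linear-trend assumption.

    Within each week the seven daily values lie on a line centred on the
    weekly mean; the slope comes from the neighbouring weekly means (one-sided
    at the edges), so a flat weekly series reduces to count/7 while trending
    series get a continuous piecewise-linear profile. Each week's seven values
    sum exactly to its total. Negative interpolants (possible when adjacent
    weeks differ sharply) are clipped to zero and the week's remaining mass is
    renormalised, with a logged warning.
    """
    c = weekly.count
    n = len(c)
    m = c / 7.0
    if n == 1:
        log.warning(
            "single-week series %r: falling back to uniform count/7", weekly.label
        )
        slope = np.zeros(1)
    else:
        slope = np.empty(n)
        slope[0] = (m[1] - m[0]) / 7.0
        slope[-1] = (m[-1] - m[-2]) / 7.0
        if n > 2:
            slope[1:-1] = (m[2:] - m[:-2]) / 14.0
    offsets = np.arange(7.0) - 3.0
    daily = m[:, None] + slope[:, None] * offsets[None, :]  # (n, 7)

    negative_weeks = np.nonzero((daily < 0).any(axis=1))[0]
    for i in negative_weeks:
        week = np.clip(daily[i], 0.0, None)
        pos = week.sum()
        daily[i] = week * (c[i] / pos) if pos > 0 else np.full(7, m[i])
    if negative_weeks.size:
        log.warning(
            "disaggregation of %r produced negative interpolants in %d week(s); "
            "clipped to 0 and renormalised",
            weekly.label,
            negative_weeks.size,
        )

    dates = pd.date_range(weekly.week_start[0], periods=7 * n, freq="D")
    return DailySeries(dates, daily.ravel(), interpolated=True, label=weekly.label)


def disaggregation_matrix(n_weeks: int) -> np.ndarray:
    """Linear operator of the disaggregation: daily (7n) x weekly (n).

    Row d, column w gives the weight of weekly total w in disaggregated day
    d, for the centred mass-preserving scheme (ignoring the rare
    negative-clipping branch). Used to propagate weekly count noise through
    the filter when building model-based variances.
    """
    n = int(n_weeks)
    L = np.zeros((7 * n, n))
    j = np.arange(7.0) - 3.0
    for i in range(n):
        L[7 * i : 7 * i + 7, i] += 1.0 / 7.0
        if n == 1:
            continue
        if i == 0:
            pairs = ((1, 1 / 7), (0, -1 / 7))
        elif i == n - 1:
            pairs = ((n - 1, 1 / 7), (n - 2, -1 / 7))
        else:
            pairs = ((i + 1, 1 / 14), (i - 1, -1 / 14))
        for col, w in pairs:
            L[7 * i : 7 * i + 7, col] += j * (w / 7.0)
    return L


def lag_aligned_filter(
    daily: DailySeries, anchor, lag: int
) -> tuple[DailySeries, WeeklySeries]:
    """Weekly-aggregate-and-disaggregate a daily series with lag-aligned bins.

    When the outcome is only observed as weekly totals, its disaggregated
    daily values carry the weekly smoothing filter; regressing them on an
    unfiltered daily exposure attenuates the structural coefficient. The fix
    is to pass the exposure through the *same* filter, with 7-day bins placed
    so that, after the outcome is shifted by ``lag`` days, the two filters
    coincide on the panel's time axis: bins start at day offsets congruent to
    ``-lag (mod 7)`` from ``anchor`` (the outcome's first registration week
    start). Only complete bins inside the data range are used.

    Returns the filtered daily series together with the weekly totals it was
    built from (the latter feed the model-based variance).
    """
    anchor = pd.Timestamp(anchor).normalize()
    offset0 = (-int(lag)) % 7
    # earliest bin start >= first date with start ≡ offset0 (mod 7) vs anchor
    first_rel = (daily.date[0] - anchor).days
    shift = (offset0 - first_rel) % 7
    start_idx = int(shift)
    n_full = (len(daily) - start_idx) // 7
    if n_full < 1:
        raise ValidationError("series too short for one complete 7-day bin")
    vals = daily.value[start_idx : start_idx + 7 * n_full]
    weekly = WeeklySeries(
        pd.date_range(daily.date[start_idx], periods=n_full, freq="7D"),
        vals.reshape(n_full, 7).sum(axis=1),
        label=daily.label,
    )
    return disaggregate_weekly_to_daily(weekly), weekly


def reaggregate_to_weekly(daily: DailySeries) -> WeeklySeries:
    """Sum a daily series back into consecutive 7-day weeks from its first date."""
    n_weeks = len(daily) // 7
    if n_weeks == 0:
        raise ValidationError("need at least 7 daily values to form a week")
    values = daily.value[: 7 * n_weeks].reshape(n_weeks, 7).sum(axis=1)
    starts = daily.date[0] + pd.to_timedelta(7 * np.arange(n_weeks), unit="D")
    return WeeklySeries(pd.DatetimeIndex(starts), values, label=daily.label)


def scale_series(daily: DailySeries, factor: float) -> DailySeries:
    """Multiply every value by ``factor`` (e.g. the x3 sentinel-coverage scaling)."""
    factor = float(factor)
    if not factor > 0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    return DailySeries(
        daily.date, daily.value * factor, daily.interpolated, daily.label
    )


def align_calendar(
    current: DailySeries, historical: DailySeries, window: StudyWindow
) -> pd.DataFrame:
    """Pair current and historical daily values on a day-offset axis.

    Both series are restricted to the study window and keyed by day offset
    from ``window_start``. If exactly one of the two lacks February 29 (a
    comparator averaged over non-leap years), the leap day is dropped from the
    other so the offset axes match. Missing dates elsewhere raise
    :class:`CoverageError` listing them.

    Returns a frame with columns ``offset, date, current, historical``.
    """
    cur = current.between(window.window_start, window.window_end)
    hist = historical.between(window.window_start, window.window_end)

    expected = pd.date_range(window.window_start, window.window_end, freq="D")
    for name, series in (("current", cur), ("historical", hist)):
        missing = expected.difference(series.date)
        missing = missing[~_is_feb29(pd.DatetimeIndex(missing))]
        if len(missing):
            shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise CoverageError(
                f"{name} series does not cover the study window; "
                f"missing: {shown}{more}",
                missing=list(missing),
            )

    cur_feb29 = _is_feb29(cur.date)
    hist_feb29 = _is_feb29(hist.date)
    if cur_feb29.any() and not hist_feb29.any():
        cur = DailySeries(
            cur.date[~cur_feb29], cur.value[~cur_feb29],
            cur.interpolated[~cur_feb29], cur.label,
        )
    elif hist_feb29.any() and not cur_feb29.any():
        hist = DailySeries(
            hist.date[~hist_feb29], hist.value[~hist_feb29],
            hist.interpolated[~hist_feb29], hist.label,
        )

    if len(cur) != len(hist):
        raise CoverageError(
            f"aligned lengths differ: {len(cur)} current vs {len(hist)} historical"
        )
    return pd.DataFrame(
        {
            "offset": np.arange(len(cur)),
            "date": cur.date,
            "current": cur.value,
            "historical": hist.value,
        }
    )
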