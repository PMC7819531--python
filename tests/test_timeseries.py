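import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdid import (
    CoverageError,
    DailySeries,
    ValidationError,
    WeeklySeries,
    align_calendar,
    disaggregate_weekly_to_daily,
    lag_aligned_filter,
    read_count_series,
    reaggregate_to_weekly,
    scale_series,
)
from ivdid.timeseries import StudyWindow, disaggregation_matrix


def _write(tmp_path, text, name="series.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadCountSeries:
    def test_weekly_two_rows(self, tmp_path):
        path = _write(tmp_path, "date,count\n2020-01-01,70\n2020-01-08,140\n")
        s = read_count_series(path, "weekly")
        assert isinstance(s, WeeklySeries)
        assert len(s) == 2
        assert s.count.tolist() == [70.0, 140.0]

    def test_rows_sorted_by_date(self, tmp_path):
        path = _write(tmp_path, "date,count\n2020-01-08,140\n2020-01-01,70\n")
        s = read_count_series(path, "weekly")
        assert s.count.tolist() == [70.0, 140.0]

    @pytest.mark.parametrize(
        "text,match",
        [
            ("date,count\n2020-01-01,-4\n2020-01-08,3\n", "negative"),
            ("date,count\n2020-01-01,70\n2020-01-07,70\n", "7 days apart"),
            ("date,count\n2020-01-01,70\n2020-01-01,70\n", "duplicate"),
            ("date,count\n2020-01-01,seventy\n2020-01-08,70\n", "non-numeric"),
            ("when,count\n2020-01-01,70\n", "date"),
            ("date,n\n2020-01-01,70\n", "count"),
        ],
    )
    def test_invalid_weekly_files(self, tmp_path, text, match):
        path = _write(tmp_path, text)
        with pytest.raises(ValidationError, match=match):
            read_count_series(path, "weekly")

    def test_daily_with_interpolated_flags(self, tmp_path):
        path = _write(
            tmp_path,
            "date,value,interpolated\n2020-01-01,5,true\n2020-01-02,6,false\n",
        )
        s = read_count_series(path, "daily")
        assert isinstance(s, DailySeries)
        assert s.interpolated.tolist() == [True, False]

    def test_daily_gap_rejected(self, tmp_path):
        path = _write(tmp_path, "date,value\n2020-01-01,5\n2020-01-03,6\n")
        with pytest.raises(ValidationError, match="gap"):
            read_count_series(path, "daily")

    def test_daily_missing_feb29_allowed(self):
        # a 5-year averaged comparator has no leap day
        dates = pd.date_range("2020-02-27", "2020-03-02").drop(
            pd.Timestamp("2020-02-29")
        )
        s = DailySeries(dates, np.ones(4))
        assert len(s) == 4


class TestDisaggregation:
    def test_constant_weeks_give_flat_days(self, weekly_constant):
        d = disaggregate_weekly_to_daily(weekly_constant)
        assert np.allclose(d.value, 10.0)
        assert d.interpolated.all()

    def test_single_week_uniform_fallback(self):
        w = WeeklySeries(pd.DatetimeIndex(["2020-01-01"]), [70.0])
        d = disaggregate_weekly_to_daily(w)
        assert np.allclose(d.value, 10.0)

    def test_two_weeks_match_constrained_line_oracle(self):
        # Independent oracle: with two weeks the trend is one global line
        # a + b*j; solve the 2x2 linear system given by the two weekly sums.
        w = WeeklySeries(pd.date_range("2020-01-01", periods=2, freq="7D"),
                         [70.0, 140.0])
        A = np.array([[7.0, sum(range(0, 7))], [7.0, sum(range(7, 14))]])
        a, b = np.linalg.solve(A, np.array([70.0, 140.0]))
        oracle = a + b * np.arange(14.0)
        d = disaggregate_weekly_to_daily(w)
        assert np.allclose(d.value, oracle, atol=1e-12)
        assert np.isclose(d.value[:7].sum(), 70.0)
        assert np.isclose(d.value[7:].sum(), 140.0)

    def test_negative_interpolants_clipped_and_renormalised(self):
        # steep drop forces the line below zero in the low week
        w = WeeklySeries(pd.date_range("2020-01-01", periods=3, freq="7D"),
                         [700.0, 7.0, 700.0])
        d = disaggregate_weekly_to_daily(w)
        assert (d.value >= 0).all()
        sums = d.value.reshape(3, 7).sum(axis=1)
        assert np.allclose(sums, w.count, atol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(
            st.floats(0, 1e5, allow_nan=False, allow_infinity=False),
            min_size=2, max_size=12,
        )
    )
    def test_mass_conservation_property(self, counts):
        w = WeeklySeries(
            pd.date_range("2019-11-01", periods=len(counts), freq="7D"), counts
        )
        d = disaggregate_weekly_to_daily(w)
        sums = d.value.reshape(len(counts), 7).sum(axis=1)
        assert np.allclose(sums, w.count, atol=1e-9)

    def test_weekly_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        w = WeeklySeries(pd.date_range("2019-11-01", periods=8, freq="7D"),
                         rng.uniform(50, 500, 8))
        back = reaggregate_to_weekly(disaggregate_weekly_to_daily(w))
        assert np.allclose(back.count, w.count, atol=1e-9)
        assert (back.week_start == w.week_start).all()

    def test_matrix_matches_function(self):
        rng = np.random.default_rng(3)
        counts = rng.uniform(100, 900, 6)
        w = WeeklySeries(pd.date_range("2020-01-01", periods=6, freq="7D"), counts)
        d = disaggregate_weekly_to_daily(w)
        assert np.allclose(disaggregation_matrix(6) @ counts, d.value, atol=1e-9)


class TestScaleSeries:
    def test_factor_three_triples_values(self):
        s = DailySeries(pd.date_range("2020-01-01", periods=3), [1.0, 2.0, 3.0])
        assert scale_series(s, 3.0).value.tolist() == [3.0, 6.0, 9.0]

    def test_identity_and_zero(self):
        s = DailySeries(pd.date_range("2020-01-01", periods=3), [0.0, 0.0, 0.0])
        assert scale_series(s, 1.0).value.tolist() == s.value.tolist()
        assert scale_series(s, 9.0).value.tolist() == [0.0, 0.0, 0.0]

    @given(a=st.floats(0.1, 10), b=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_scaling_composes_multiplicatively(self, a, b):
        s = DailySeries(pd.date_range("2020-01-01", periods=4), [1.0, 2.0, 3.0, 4.0])
        once = scale_series(s, a * b)
        twice = scale_series(scale_series(s, a), b)
        assert np.allclose(once.value, twice.value, rtol=1e-12)

    def test_nonpositive_factor_rejected(self):
        s = DailySeries(pd.date_range("2020-01-01", periods=2), [1.0, 2.0])
        for bad in (0.0, -1.0):
            with pytest.raises(ValidationError):
                scale_series(s, bad)


class TestAlignCalendar:
    def _series(self, start, end, value=1.0, drop_feb29=False):
        dates = pd.date_range(start, end)
        if drop_feb29:
            dates = dates[~((dates.month == 2) & (dates.day == 29))]
        return DailySeries(dates, np.full(len(dates), value))

    def test_full_window_gives_120_rows(self, window):
        cur = self._series("2019-12-18", "2020-04-15")
        hist = self._series("2019-12-18", "2020-04-15", 2.0)
        tab = align_calendar(cur, hist, window)
        assert len(tab) == 120
        assert tab["offset"].tolist() == list(range(120))

    def test_comparator_without_feb29_gives_119_rows(self, window):
        cur = self._series("2019-12-18", "2020-04-15")
        hist = self._series("2019-12-18", "2020-04-15", 2.0, drop_feb29=True)
        tab = align_calendar(cur, hist, window)
        assert len(tab) == 119
        assert pd.Timestamp("2020-02-29") not in set(tab["date"])

    def test_missing_month_raises_coverage_error(self, window):
        cur = self._series("2019-12-18", "2020-04-15")
        hist = self._series("2020-02-01", "2020-04-15", 2.0)
        with pytest.raises(CoverageError, match="2019-12"):
            align_calendar(cur, hist, window)

    def test_identical_series_pair_equal(self, window):
        cur = self._series("2019-12-18", "2020-04-15", 5.0)
        tab = align_calendar(cur, cur, window)
        assert (tab["current"] == tab["historical"]).all()


class TestLagAlignedFilter:
    def test_bins_shift_with_lag(self):
        dates = pd.date_range("2019-12-11", periods=35)
        s = DailySeries(dates, np.arange(35.0) + 10.0)
        anchor = pd.Timestamp("2019-12-18")
        for lag in (0, 3, 10):
            filtered, weekly = lag_aligned_filter(s, anchor, lag)
            start_off = (weekly.week_start[0] - anchor).days
            assert start_off % 7 == (-lag) % 7
            # filter conserves mass over its bins
            assert np.isclose(filtered.value.sum(), weekly.count.sum(), atol=1e-9)

    def test_linear_series_unchanged_in_interior(self):
        # the filter reproduces an exactly linear series away from the edges
        dates = pd.date_range("2020-01-01", periods=42)
        s = DailySeries(dates, 100.0 + 2.0 * np.arange(42.0))
        filtered, _ = lag_aligned_filter(s, dates[0], 0)
        assert np.allclose(filtered.value[7:-7], s.value[7:-7], atol=1e-9)


class TestStudyWindow:
    def test_cutoff_must_be_inside(self):
        with pytest.raises(ValidationError):
            StudyWindow("2020-01-01", "2020-02-01", "2020-02-01")

    def test_n_days_inclusive(self, window):
        assert window.n_days == 120
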