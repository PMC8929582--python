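"""Calendar handling, validation and period aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pyra import (
    CycleConfig,
    DailySeries,
    aggregate_periods,
    load_detections_csv,
    strip_leap_days,
    synthetic_dates,
    validate_series,
    write_detections_csv,
)


def frame(dates, values=None, lf=None, site="s"):
    n = len(dates)
    return pd.DataFrame(
        {
            "site_id": site,
            "date": dates,
            "value": np.arange(n, dtype=float) if values is None else values,
            "logged_fraction": np.ones(n) if lf is None else lf,
        }
    )


class TestStripLeapDays:
    def test_four_years_spanning_leap_year(self):
        dates = pd.date_range("2015-06-01", periods=1461, freq="D")  # crosses 2016-02-29
        series = strip_leap_days(frame(dates.strftime("%Y-%m-%d")))
        assert len(series) == 1460
        assert series.day_index[0] == 1
        assert series.day_index[-1] == 1460
        assert np.all(np.diff(series.day_index) == 1)

    def test_leap_free_input_is_identity(self):
        dates = pd.date_range("2017-01-01", periods=365, freq="D")
        vals = np.random.default_rng(1).uniform(0, 9, 365)
        series = strip_leap_days(frame(dates.strftime("%Y-%m-%d"), vals))
        assert len(series) == 365
        np.testing.assert_array_equal(series.value, vals)
        np.testing.assert_array_equal(series.day_index, np.arange(1, 366))

    def test_day_of_cycle_shifts_after_feb29_removed(self):
        # 366 consecutive dates including 2020-02-29: after stripping, the day
        # following Feb 29 sits one position earlier in the cycle
        dates = pd.date_range("2020-01-01", periods=366, freq="D")
        series = strip_leap_days(frame(dates.strftime("%Y-%m-%d")))
        assert len(series) == 365
        mar1 = np.flatnonzero(series.date == np.datetime64("2020-03-01"))[0]
        with_feb29_position = (np.datetime64("2020-03-01") - np.datetime64("2020-01-01")).astype(int) + 1
        assert series.day_of_cycle[mar1] == with_feb29_position - 1 == 60

    def test_alignment_across_years_after_stripping(self):
        # same month-day in successive years has the same day_of_cycle even
        # across an intervening Feb 29
        dates = pd.date_range("2019-07-01", periods=800, freq="D")
        series = strip_leap_days(frame(dates.strftime("%Y-%m-%d")))
        d0 = np.flatnonzero(series.date == np.datetime64("2019-10-10"))[0]
        d1 = np.flatnonzero(series.date == np.datetime64("2020-10-10"))[0]
        assert series.day_of_cycle[d0] == series.day_of_cycle[d1]

    def test_duplicate_date_rejected(self):
        dates = ["2020-01-01", "2020-01-02", "2020-01-02"]
        with pytest.raises(ValueError, match="duplicate"):
            strip_leap_days(frame(dates))

    def test_unparseable_date_rejected(self):
        with pytest.raises(ValueError, match="date"):
            strip_leap_days(frame(["2020-01-01", "not-a-date", "2020-01-03"]))

    def test_gaps_preserve_calendar_day_index(self):
        dates = ["2021-01-01", "2021-01-05", "2021-03-01"]
        series = strip_leap_days(frame(dates))
        np.testing.assert_array_equal(series.day_index, [1, 5, 60])

    @given(
        start=st.dates(min_value=pd.Timestamp("2017-03-01").date(),
                       max_value=pd.Timestamp("2018-06-01").date()),
        n=st.integers(min_value=1, max_value=200),
    )
    def test_roundtrip_on_leap_free_span(self, start, n):
        # within 2017-03-01 .. 2019-02-28 there is no Feb 29
        dates = pd.date_range(str(start), periods=n, freq="D")
        series = strip_leap_days(frame(dates.strftime("%Y-%m-%d")))
        assert len(series) == n
        np.testing.assert_array_equal(series.day_index, np.arange(1, n + 1))


class TestDailySeries:
    def test_cycle_indexing(self):
        s = DailySeries("s", CycleConfig(C=10), [1, 10, 11, 25], [1, 1, 1, 1], [1, 1, 1, 1])
        np.testing.assert_array_equal(s.cycle_index, [1, 1, 2, 3])
        np.testing.assert_array_equal(s.day_of_cycle, [1, 10, 1, 5])

    def test_duplicate_day_index_rejected(self):
        with pytest.raises(ValueError, match="day_index"):
            DailySeries("s", CycleConfig(), [1, 2, 2], [0, 0, 0], [1, 1, 1])

    def test_logged_fraction_bounds(self):
        with pytest.raises(ValueError, match="logged_fraction"):
            DailySeries("s", CycleConfig(), [1], [0.0], [1.5])

    def test_cycle_config_validation(self):
        with pytest.raises(ValueError):
            CycleConfig(C=1)
        with pytest.raises(ValueError):
            CycleConfig(full_log_threshold=0.0)


class TestValidateSeries:
    def test_all_complete(self):
        s = DailySeries("s", CycleConfig(), np.arange(1, 1461), np.ones(1460), np.ones(1460))
        report = validate_series(s)
        assert report.n_fully_logged == 1460
        assert report.gap_runs == []
        assert report.ok

    def test_partial_day_below_threshold(self):
        s = DailySeries("s", CycleConfig(), [1, 2, 3], [1, 1, 1], [1.0, 0.5, 1.0])
        assert validate_series(s).n_fully_logged == 2

    def test_gap_runs_and_value_errors(self):
        s = DailySeries("s", CycleConfig(), [1, 2, 10, 11], [1, -3, np.nan, 1], [1, 1, 1, 1])
        report = validate_series(s)
        assert report.gap_runs == [7]
        assert not report.ok
        assert any("negative" in e for e in report.errors)
        assert any("non-finite" in e for e in report.errors)


class TestCsvRoundTrip:
    def test_write_then_load(self, tmp_path, two_cycle_series):
        path = tmp_path / "dets.csv"
        write_detections_csv(two_cycle_series, path)
        loaded = load_detections_csv(path)["siteA"]
        np.testing.assert_array_equal(loaded.day_index, two_cycle_series.day_index)
        np.testing.assert_allclose(loaded.value, two_cycle_series.value)

    def test_logged_minutes_column(self, tmp_path):
        path = tmp_path / "m.csv"
        pd.DataFrame(
            {"site_id": "x", "date": ["2020-01-01", "2020-01-02"],
             "value": [3.0, 4.0], "logged_minutes": [1440, 720]}
        ).to_csv(path, index=False)
        s = load_detections_csv(path)["x"]
        np.testing.assert_allclose(s.logged_fraction, [1.0, 0.5])

    def test_synthetic_dates_skip_feb29(self):
        d = synthetic_dates(np.arange(1, 1461), "2003-01-01")  # crosses 2004-02-29
        assert len(np.unique(d)) == 1460
        months = pd.DatetimeIndex(d)
        assert not (((months.month == 2) & (months.day == 29)).any())


class TestAggregatePeriods:
    def test_identical_days_two_bins(self):
        s = DailySeries("s", CycleConfig(), np.arange(1, 61), np.full(60, 8.0), np.ones(60))
        agg = aggregate_periods(s, 30)
        assert len(agg) == 2
        np.testing.assert_allclose(agg.value, [8.0, 8.0])
        np.testing.assert_allclose(agg.logged_fraction, [1.0, 1.0])
        assert agg.cycle_config.unit == "period"
        assert agg.cycle_config.C == 12

    def test_bin_without_fully_logged_days_is_absent(self):
        lf = np.ones(60)
        lf[30:] = 0.2  # second bin has no fully logged day
        s = DailySeries("s", CycleConfig(), np.arange(1, 61), np.full(60, 8.0), lf)
        agg = aggregate_periods(s, 30)
        np.testing.assert_array_equal(agg.day_index, [1])

    def test_monthly_gaps_yield_55_usable_periods(self):
        # 64 consecutive 30-day periods of daily data with 9 whole periods
        # unlogged -> 55 usable periods, a typical multi-year deployment shape
        n = 64 * 30
        lf = np.ones(n)
        missing = [3, 10, 11, 20, 33, 40, 47, 55, 60]
        for m in missing:
            lf[m * 30:(m + 1) * 30] = 0.0
        s = DailySeries("s", CycleConfig(), np.arange(1, n + 1), np.ones(n), lf)
        agg = aggregate_periods(s, 30)
        assert len(agg) == 55

    def test_partial_bin_fraction_feeds_pairing_threshold(self):
        lf = np.ones(30)
        lf[:12] = 0.0  # 18/30 fully logged days
        s = DailySeries("s", CycleConfig(), np.arange(1, 31), np.ones(30), lf)
        agg = aggregate_periods(s, 30, bin_log_threshold=0.5)
        np.testing.assert_allclose(agg.logged_fraction, [0.6])
        assert agg.fully_logged.all()
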