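"""Logger ingest, diel segmentation, rain detection."""

import io
from datetime import date, time

import numpy as np
import pandas as pd
import pytest

from rhizoflux import timeseries as ts


def make_series(thetas_by_depth, start="2022-04-01", interval_min=15):
    idx = pd.date_range(start, periods=len(next(iter(thetas_by_depth.values()))),
                        freq=pd.Timedelta(minutes=interval_min))
    frame = pd.DataFrame(thetas_by_depth, index=idx)
    frame.index.name = "timestamp"
    return ts.MoistureSeries(data=frame, interval=pd.Timedelta(minutes=interval_min))


class TestReadCsv:
    def test_three_row_identity_ingest(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text(
            "timestamp,depth_cm,theta\n"
            "2022-04-01T00:00:00,15,0.30\n"
            "2022-04-01T00:15:00,15,0.31\n"
            "2022-04-01T00:30:00,15,0.32\n"
        )
        series = ts.read_moisture_csv(csv)
        assert series.depths == [15.0]
        np.testing.assert_allclose(series.data[15.0].to_numpy(), [0.30, 0.31, 0.32])

    def test_percent_dialect_scales_to_fraction(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text(
            "timestamp,depth_cm,theta\n2022-04-01T00:00:00,15,30.0\n"
            "2022-04-01T00:15:00,15,30.5\n"
        )
        series = ts.read_moisture_csv(csv, theta_unit="percent")
        assert series.data[15.0].iloc[0] == pytest.approx(0.30)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        series = make_series({15.0: 0.3 + 0.01 * rng.standard_normal(96),
                              30.0: 0.35 + 0.01 * rng.standard_normal(96)})
        path = tmp_path / "out.csv"
        ts.write_moisture_csv(series, path)
        back = ts.read_moisture_csv(path)
        pd.testing.assert_frame_equal(back.data, series.data, check_freq=False)

    def test_unparseable_timestamp_is_format_error(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text("timestamp,depth_cm,theta\nnot-a-time,15,0.3\n")
        with pytest.raises(ts.SeriesFormatError):
            ts.read_moisture_csv(csv)

    def test_theta_out_of_range_names_row(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text(
            "timestamp,depth_cm,theta\n2022-04-01T00:00:00,15,0.3\n"
            "2022-04-01T00:15:00,15,150.0\n"
        )
        with pytest.raises(ts.SeriesValidationError, match="1"):
            ts.read_moisture_csv(csv)

    def test_gap_policy(self, tmp_path):
        # one missing step is interpolated; a 4-step hole stays missing
        times = pd.date_range("2022-04-01", periods=12, freq="15min")
        keep = [0, 1, 3, 4, 5, 10, 11]  # gap of 1 at idx 2; gap of 4 at 6-9
        rows = ["timestamp,depth_cm,theta"] + [
            f"{times[i].isoformat()},15,{0.30 + 0.001 * i:.4f}" for i in keep
        ]
        csv = tmp_path / "m.csv"
        csv.write_text("\n".join(rows) + "\n")
        series = ts.read_moisture_csv(csv)
        col = series.data[15.0]
        assert col.loc[times[2]] == pytest.approx(0.302, abs=1e-9)
        assert col.loc[times[6:10]].isna().all()


class TestSegmentDiel:
    def test_constant_series_all_boundaries_equal(self):
        series = make_series({15.0: np.full(3 * 96, 0.30)})
        w = ts.segment_diel(series, date(2022, 4, 2))[15.0]
        assert (w.theta0, w.theta1, w.theta2, w.theta3) == (0.30, 0.30, 0.30, 0.30)
        assert w.valid and w.t0 < w.t1 < w.t2 < w.t3

    def test_piecewise_linear_daytime_drop(self):
        # flat nights at 0.30 / 0.28, linear drop 06:00-20:00 on the middle day
        idx = pd.date_range("2022-04-01", periods=3 * 96, freq="15min")
        t1 = pd.Timestamp("2022-04-02 06:00")
        t2 = pd.Timestamp("2022-04-02 20:00")
        frac = ((idx - t1) / (t2 - t1)).to_numpy().clip(0, 1)
        series = make_series({15.0: 0.30 - 0.02 * frac})
        w = ts.segment_diel(series, date(2022, 4, 2), boundary_window=pd.Timedelta(0))[15.0]
        assert w.theta1 == pytest.approx(0.30)
        assert w.theta2 == pytest.approx(0.28)
        assert w.theta0 == pytest.approx(w.theta1)
        assert w.theta3 == pytest.approx(w.theta2)

    def test_boundary_mean_within_window_extremes(self):
        rng = np.random.default_rng(5)
        theta = 0.3 + 0.01 * rng.standard_normal(3 * 96)
        series = make_series({15.0: theta})
        w = ts.segment_diel(series, date(2022, 4, 2))[15.0]
        col = series.data[15.0]
        for t, th in [(w.t0, w.theta0), (w.t1, w.theta1), (w.t2, w.theta2), (w.t3, w.theta3)]:
            window = col.loc[t - pd.Timedelta(minutes=60): t + pd.Timedelta(minutes=60)]
            assert window.min() <= th <= window.max()

    def test_independent_of_input_ordering(self):
        rng = np.random.default_rng(7)
        times = pd.date_range("2022-04-01", periods=3 * 96, freq="15min")
        long = pd.DataFrame(
            {"timestamp": times, "depth_cm": 15.0, "theta": 0.3 + 0.01 * rng.standard_normal(times.size)}
        )
        shuffled = long.sample(frac=1.0, random_state=11)
        a = ts.segment_diel(ts.regularize(long), date(2022, 4, 2))[15.0]
        b = ts.segment_diel(ts.regularize(shuffled), date(2022, 4, 2))[15.0]
        assert a == b

    def test_insufficient_coverage_raises(self):
        series = make_series({15.0: np.full(96, 0.3)})  # one day only
        with pytest.raises(ts.WindowIncompleteError):
            ts.segment_diel(series, date(2022, 4, 1))

    def test_all_missing_boundary_flags_invalid(self):
        theta = np.full(3 * 96, 0.30)
        series = make_series({15.0: theta})
        # knock out the full boundary window around dawn of day 2
        series.data.loc[
            pd.Timestamp("2022-04-02 01:45"): pd.Timestamp("2022-04-02 10:15"), 15.0
        ] = np.nan
        w = ts.segment_diel(series, date(2022, 4, 2))[15.0]
        assert not w.valid


class TestRainDetection:
    def test_monotone_drying_has_no_events(self):
        series = make_series({15.0: np.linspace(0.40, 0.30, 4 * 96)})
        assert ts.detect_rain_events(series) == []

    def test_single_step_detected_with_magnitude(self):
        theta = np.full(2 * 96, 0.30)
        theta[100:] = 0.37
        series = make_series({15.0: theta})
        events = ts.detect_rain_events(series)
        assert len(events) == 1
        assert events[0].magnitude >= 0.069  # smoothing shaves the exact step a little

    def test_two_separated_pulses_two_events(self):
        theta = np.full(6 * 96, 0.30)
        theta[96:] += 0.05
        theta[4 * 96:] += 0.05
        series = make_series({15.0: theta})
        events = ts.detect_rain_events(series)
        assert len(events) == 2

    def test_simulated_two_rain_pulses(self, two_rains_result):
        from rhizoflux import sample_sensors

        series = sample_sensors(two_rains_result)
        events = ts.detect_rain_events(series)
        assert len(events) == 2
        starts = [e.start for e in events]
        forcing_days = [s for s, _, _ in two_rains_result.scenario.rain_events]
        t0 = pd.Timestamp(two_rains_result.scenario.start)
        for ev_start, day in zip(starts, forcing_days):
            onset = t0 + pd.Timedelta(days=day)
            assert onset <= ev_start <= onset + pd.Timedelta(days=2)
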