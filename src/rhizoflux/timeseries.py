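"""Soil-moisture logger series: ingest, regularization, diel segmentation.

Field loggers record volumetric water content theta at fixed depths on a
regular interval (15 min in the study design this package targets).  The
diel mass-balance estimator needs, for each calendar day and depth, the
water contents at four boundaries: preceding-night start t0, dawn t1,
dusk t2 and following-night end t3.  Night-time storage change measures
vertical soil-water flow (roots are assumed quiescent at night), so these
boundaries are what turns a raw series into an uptake estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_t, time as time_t, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_INTERVAL = pd.Timedelta(minutes=15)
DEFAULT_DAY_START = time_t(6, 0)
DEFAULT_DAY_END = time_t(20, 0)


class SeriesFormatError(ValueError):
    """Unparseable or structurally invalid moisture input."""


class SeriesValidationError(ValueError):
    """Values outside physical range (theta, depth)."""


class WindowIncompleteError(ValueError):
    """The series does not cover the requested diel window."""


@dataclass
class MoistureSeries:
    """Regular-interval volumetric water content per depth.

    ``data`` is a wide frame: DatetimeIndex on a strict regular grid,
    one float column per sensor depth (cm, positive downward), values
    theta as fractions in [0, 1] (NaN where a gap was too long to fill).
    """

    data: pd.DataFrame
    interval: pd.Timedelta = DEFAULT_INTERVAL
    meta: dict = field(default_factory=dict)

    @property
    def depths(self) -> list[float]:
        return sorted(float(c) for c in self.data.columns)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise SeriesFormatError("MoistureSeries needs a DatetimeIndex")
        if self.data.index.has_duplicates:
            raise SeriesFormatError("duplicate timestamps in series")
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()
        self.data = self.data[sorted(self.data.columns, key=float)]
        vals = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise SeriesValidationError("theta outside [0, 1] after scaling")


@dataclass(frozen=True)
class DielWindow:
    """One day's boundary segmentation at one depth (times in days internally).

    t0 < t1 < t2 < t3 bracket preceding night, daytime, and following
    night; Theta0..Theta3 are (window-averaged) water contents at those
    boundaries.  ``valid`` is False when a boundary window had no usable
    samples.
    """

    date: date_t
    depth: float
    t0: pd.Timestamp
    t1: pd.Timestamp
    t2: pd.Timestamp
    t3: pd.Timestamp
    theta0: float
    theta1: float
    theta2: float
    theta3: float
    valid: bool = True
    rain_flag: bool = False

    @property
    def night1_days(self) -> float:
        return (self.t1 - self.t0) / pd.Timedelta(days=1)

    @property
    def day_days(self) -> float:
        return (self.t2 - self.t1) / pd.Timedelta(days=1)

    @property
    def night2_days(self) -> float:
        return (self.t3 - self.t2) / pd.Timedelta(days=1)


@dataclass(frozen=True)
class RainEvent:
    start: pd.Timestamp
    depth: float
    magnitude: float  # delta-theta (fraction), > 0


def regularize(
    long_df: pd.DataFrame,
    interval: pd.Timedelta = DEFAULT_INTERVAL,
    max_gap_intervals: int = 2,
    meta: dict | None = None,
) -> MoistureSeries:
    """Long (timestamp, depth_cm, theta) records -> regular wide series.

    Timestamps are snapped to the interval grid; gaps of up to
    ``max_gap_intervals`` missing steps are filled by linear
    interpolation, longer gaps stay NaN (the affected diel windows are
    later flagged invalid rather than guessed at).
    """
    df = long_df.copy()
    if (df["depth_cm"] <= 0).any():
        raise SeriesValidationError("depth_cm must be > 0")
    wide = df.pivot_table(index="timestamp", columns="depth_cm", values="theta")
    idx = pd.date_range(wide.index.min(), wide.index.max(), freq=interval)
    wide = wide.reindex(wide.index.union(idx))
    filled = wide.interpolate(method="time", limit_area="inside")
    # fill only gaps of <= max_gap_intervals missing steps; longer runs
    # stay missing (their diel windows are flagged, not guessed at)
    for col in wide.columns:
        isna = wide[col].isna()
        run_id = (~isna).cumsum()
        run_len = isna.groupby(run_id).transform("sum")
        ok = isna & (run_len <= max_gap_intervals)
        wide.loc[ok, col] = filled.loc[ok, col]
    wide = wide.reindex(idx)
    wide.columns = [float(c) for c in wide.columns]
    wide.index.name = "timestamp"
    return MoistureSeries(data=wide, interval=interval, meta=meta or {})


def read_moisture_csv(
    path,
    theta_unit: str = "fraction",
    interval: pd.Timedelta = DEFAULT_INTERVAL,
    max_gap_intervals: int = 2,
    column_map: dict | None = None,
) -> MoistureSeries:
    """Read a long-format logger CSV (columns timestamp, depth_cm, theta).

    ``theta_unit`` is an explicit dialect flag: "percent" values (0-100)
    are scaled to fractions; internal representation is always fraction.
    ``column_map`` renames source columns to the canonical trio.
    """
    if theta_unit not in ("fraction", "percent"):
        raise SeriesFormatError(f"unknown theta unit {theta_unit!r}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"timestamp", "depth_cm", "theta"} - set(df.columns)
    if missing:
        raise SeriesFormatError(f"missing columns: {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesFormatError(f"unparseable timestamp in {path}: {exc}") from exc
    theta = pd.to_numeric(df["theta"], errors="coerce")
    bad = df.index[(theta < 0) | (theta > 100) | theta.isna()]
    if len(bad):
        raise SeriesValidationError(
            f"theta outside [0, 100] or non-numeric at row(s) {list(bad[:5])}"
        )
    df["theta"] = theta / 100.0 if theta_unit == "percent" else theta
    return regularize(df, interval=interval, max_gap_intervals=max_gap_intervals)


def write_moisture_csv(series: MoistureSeries, path) -> None:
    """Write the canonical long-format CSV (round-trips through the reader)."""
    long_df = (
        series.data.stack(future_stack=True)
        .rename("theta")
        .reset_index()
        .rename(columns={"level_1": "depth_cm"})
        .dropna(subset=["theta"])
    )
    long_df["timestamp"] = long_df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    long_df.to_csv(path, index=False)


def _edge_fit(seg: pd.Series, t: pd.Timestamp) -> float:
    """Linear fit over one side of a boundary, evaluated at the boundary."""
    seg = seg.dropna()
    if seg.empty:
        return float("nan")
    if len(seg) < 3:
        return float(seg.mean())
    x = (seg.index - t) / pd.Timedelta(days=1)
    slope, intercept = np.polyfit(x, seg.to_numpy(), 1)
    return float(intercept)


def _boundary_theta(
    col: pd.Series, t: pd.Timestamp, window: pd.Timedelta
) -> float:
    """Water content at a diel boundary.

    A symmetric window mean straddles the day/night kink in theta(t) and
    biases the storage rates, so each side of the boundary is fitted
    linearly on its own and the two edge evaluations are averaged; the
    result is clamped to the window's observed range.  window = 0 gives
    a point read.
    """
    if window == pd.Timedelta(0):
        return float(col.get(t, np.nan))
    left = col.loc[t - window: t]
    right = col.loc[t: t + window]
    sides = [v for v in (_edge_fit(left, t), _edge_fit(right, t)) if np.isfinite(v)]
    if not sides:
        return float("nan")
    both = col.loc[t - window: t + window].dropna()
    return float(np.clip(np.mean(sides), both.min(), both.max()))


def segment_diel(
    series: MoistureSeries,
    date,
    day_start: time_t = DEFAULT_DAY_START,
    day_end: time_t = DEFAULT_DAY_END,
    boundary_window: pd.Timedelta = pd.Timedelta(hours=4),
    depths=None,
) -> dict[float, DielWindow]:
    """Segment one calendar day into its diel window per depth.

    Boundaries: t1/t2 are ``day_start``/``day_end`` on ``date``; t0 is the
    previous day's dusk, t3 the next day's dawn.  Theta at each boundary
    is estimated from the samples within ±``boundary_window`` by averaging
    two one-sided linear fits (a point read when the window is zero).  A
    depth whose boundary windows contain no usable samples gets
    ``valid=False`` rather than a guessed value.
    """
    day = pd.Timestamp(date).normalize()
    t0 = day - pd.Timedelta(days=1) + pd.Timedelta(hours=day_end.hour, minutes=day_end.minute)
    t1 = day + pd.Timedelta(hours=day_start.hour, minutes=day_start.minute)
    t2 = day + pd.Timedelta(hours=day_end.hour, minutes=day_end.minute)
    t3 = day + pd.Timedelta(days=1) + pd.Timedelta(hours=day_start.hour, minutes=day_start.minute)
    if not (t0 < t1 < t2 < t3):
        raise ValueError("day window must satisfy t0 < t1 < t2 < t3")
    idx = series.data.index
    if idx.min() > t0 - boundary_window or idx.max() < t3 + boundary_window - series.interval:
        raise WindowIncompleteError(
            f"series [{idx.min()} .. {idx.max()}] does not cover diel window "
            f"[{t0} .. {t3}] for {day.date()}"
        )
    out: dict[float, DielWindow] = {}
    for depth in depths if depths is not None else series.depths:
        col = series.data[float(depth)]
        thetas = [_boundary_theta(col, t, boundary_window) for t in (t0, t1, t2, t3)]
        valid = bool(np.all(np.isfinite(thetas)))
        out[float(depth)] = DielWindow(
            date=day.date(),
            depth=float(depth),
            t0=t0,
            t1=t1,
            t2=t2,
            t3=t3,
            theta0=thetas[0],
            theta1=thetas[1],
            theta2=thetas[2],
            theta3=thetas[3],
            valid=valid,
        )
    return out


def detect_rain_events(
    series: MoistureSeries,
    threshold: float = 0.01,
    window: pd.Timedelta = pd.Timedelta(hours=6),
) -> list[RainEvent]:
    """Rainfall events: topmost-depth theta rising >= threshold within window.

    The rise at time t is theta(t) minus the minimum over the trailing
    window; runs of detections closer than one window apart are merged
    into a single event whose magnitude is the largest rise seen.  The
    series is lightly smoothed (centred 5-sample mean) first so sensor
    noise cannot fake a rise.
    """
    top = min(series.depths)
    col = series.data[top].rolling(5, center=True, min_periods=1).mean()
    trailing_min = col.rolling(window, min_periods=1).min()
    rise = col - trailing_min
    mask = (rise >= threshold).to_numpy()
    times = series.data.index
    events: list[RainEvent] = []
    cur_start = None
    cur_mag = 0.0
    last_hit = None
    for i in np.flatnonzero(mask):
        t = times[i]
        if cur_start is not None and last_hit is not None and t - last_hit > window:
            events.append(RainEvent(start=cur_start, depth=top, magnitude=cur_mag))
            cur_start, cur_mag = None, 0.0
        if cur_start is None:
            cur_start = t
        cur_mag = max(cur_mag, float(rise.iloc[i]))
        last_hit = t
    if cur_start is not None:
        events.append(RainEvent(start=cur_start, depth=top, magnitude=cur_mag))
    return events


def rain_days(events: list[RainEvent]) -> set[date_t]:
    """Calendar days touched by any detected event (for flagging, not dropping)."""
    return {e.start.date() for e in events}
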