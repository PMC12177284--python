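"""Diel mass-balance root water uptake, transpiration, relative uptake.

The daily uptake rate at a sensor depth is estimated from the soil-water
storage change over the daytime, corrected for vertical soil-water flow
using the two bracketing nights (when root uptake is negligible):

    s' = (Theta1 - Theta2)/(t2 - t1)
         + 1/2 * [ (Theta1 - Theta0)/(t1 - t0) + (Theta3 - Theta2)/(t3 - t2) ]

The second term is the night-flux correction: the mean nocturnal rate of
storage change, attributed to flow across soil sections rather than to
roots.  s' has units d^-1 (water volume per soil volume per day).

Transpiration is approximated by depth-integrating s'(z) over 0-50 cm
through the three sensor depths (piecewise linear, constant extension to
the profile boundaries), and relative uptake is each layer band's share
of that integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_t

import numpy as np
import pandas as pd

from .timeseries import DielWindow


@dataclass(frozen=True)
class DailyLayerUptake:
    date: date_t
    depth: float
    s_prime: float  # d^-1
    night_correction: float  # d^-1, the bracketed half-sum
    valid: bool
    rain_flag: bool = False


@dataclass(frozen=True)
class TranspirationEstimate:
    date: date_t
    T: float  # cm d^-1, integral of s'(z) over the profile
    layer_contributions: dict  # sensor depth -> cm d^-1 over its band


@dataclass(frozen=True)
class RelativeUptake:
    date: date_t
    depth: float
    fraction: float


def daily_uptake_rate(window: DielWindow) -> DailyLayerUptake:
    """Estimate s' for one depth-day from its diel window.

    Invalid windows propagate as invalid rows (NaN rate); rain days are
    flagged by the caller, never silently dropped.  Negative s' (strong
    upward flux) is retained and left to downstream validity filters —
    clipping would bias the permeability inversion.
    """
    if not window.valid:
        return DailyLayerUptake(
            date=window.date,
            depth=window.depth,
            s_prime=float("nan"),
            night_correction=float("nan"),
            valid=False,
            rain_flag=window.rain_flag,
        )
    dt_n1, dt_day, dt_n2 = window.night1_days, window.day_days, window.night2_days
    if min(dt_n1, dt_day, dt_n2) <= 0:
        raise ZeroDivisionError("diel window has a zero-length segment")
    night = 0.5 * (
        (window.theta1 - window.theta0) / dt_n1
        + (window.theta3 - window.theta2) / dt_n2
    )
    s = (window.theta1 - window.theta2) / dt_day + night
    return DailyLayerUptake(
        date=window.date,
        depth=window.depth,
        s_prime=float(s),
        night_correction=float(night),
        valid=True,
        rain_flag=window.rain_flag,
    )


def profile_bands(sensor_depths, top: float = 0.0, bottom: float = 50.0):
    """Depth band [lo, hi] assigned to each sensor by midpoint splitting.

    For sensors at 15/30/45 cm over a 0-50 cm profile the bands are
    0-22.5, 22.5-37.5 and 37.5-50 cm.
    """
    z = sorted(float(d) for d in sensor_depths)
    edges = [top] + [(a + b) / 2.0 for a, b in zip(z[:-1], z[1:])] + [bottom]
    return {zi: (lo, hi) for zi, lo, hi in zip(z, edges[:-1], edges[1:])}


def _band_integral(z, s, lo, hi, npts=None):
    """Integral of the piecewise-linear profile through (z, s) over [lo, hi].

    The profile extends as a constant beyond the first/last sensor.
    Exact (trapezoid on the breakpoints), no quadrature grid needed.
    """
    pts = sorted({lo, hi, *[zi for zi in z if lo < zi < hi]})
    vals = np.interp(pts, z, s)  # np.interp clamps outside -> constant extension
    return float(np.trapezoid(vals, pts))


def depth_integrated_transpiration(
    uptakes: list[DailyLayerUptake],
    top: float = 0.0,
    bottom: float = 50.0,
) -> TranspirationEstimate:
    """Integrate one date's layer uptake rates to transpiration (cm d^-1).

    All layers must be valid; the per-sensor contributions are the
    integrals over the midpoint-split bands and sum exactly to T.
    """
    if not uptakes:
        raise ValueError("no uptake rows supplied")
    dates = {u.date for u in uptakes}
    if len(dates) != 1:
        raise ValueError(f"uptake rows span multiple dates: {sorted(dates)}")
    invalid = [u.depth for u in uptakes if not u.valid or not np.isfinite(u.s_prime)]
    if invalid:
        raise ValueError(f"invalid layer(s) at depth {invalid} — date skipped")
    rows = sorted(uptakes, key=lambda u: u.depth)
    z = [u.depth for u in rows]
    s = [u.s_prime for u in rows]
    bands = profile_bands(z, top, bottom)
    contrib = {zi: _band_integral(z, s, *bands[zi]) for zi in z}
    return TranspirationEstimate(
        date=rows[0].date, T=float(sum(contrib.values())), layer_contributions=contrib
    )


def normalize_uptake(est: TranspirationEstimate) -> list[RelativeUptake]:
    """Layer contributions as fractions of T; skipped (empty) when T <= 0."""
    if est.T <= 0:
        return []
    return [
        RelativeUptake(date=est.date, depth=z, fraction=c / est.T)
        for z, c in sorted(est.layer_contributions.items())
    ]


def uptake_table(rows: list[DailyLayerUptake]) -> pd.DataFrame:
    """Long output table: date, depth_cm, s_prime_per_day, night_correction_per_day, valid, rain_flag."""
    return pd.DataFrame(
        [
            {
                "date": r.date,
                "depth_cm": r.depth,
                "s_prime_per_day": r.s_prime,
                "night_correction_per_day": r.night_correction,
                "valid": r.valid,
                "rain_flag": r.rain_flag,
            }
            for r in rows
        ]
    )
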