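"""Synthetic ground truth: 1-D vertical soil-water flow with a root sink.

The simulator solves the 1-D vertical Richards equation on a finite-volume
grid (z positive downward, cm; matric head in cm of water internally)

    d(theta)/dt = d/dz [ K(psi) (d(psi)/dz - 1) ] - s(z, t)

with van Genuchten-Mualem hydraulic functions per soil horizon, a rainfall
flux top boundary, free drainage (unit hydraulic gradient) or no-flux at
the bottom, and the radial root uptake law as the sink:

    s = lambda_d * 2*pi * k_r(z) * L(z) * max(psi - psi0, 0)   [potentials in MPa]

active only inside the diurnal window.  lambda_d is a daily scalar set so
the profile-integrated sink tracks the day's transpiration demand, capped
at ``lambda_max`` — a capped multiplier makes the plant supply-limited
(uptake follows the hydraulic law) whenever demand exceeds what the root
system can extract.

Time stepping is implicit (backward Euler) with modified-Picard iteration
and adaptive step halving; after each converged step the water contents
are updated from the converged interface fluxes and sink, so the discrete
water budget closes to machine precision by construction.  Every run
records the true sink, boundary fluxes, and a mass-balance residual
series, which is what makes the simulator usable as ground truth for the
uptake estimator and the permeability inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .retention import RetentionParams
from .timeseries import MoistureSeries

#: 1 kPa of matric potential in cm of water head (g = 9.80665 m s^-2)
CM_HEAD_PER_KPA = 10.19716
CM_HEAD_PER_MPA = CM_HEAD_PER_KPA * 1000.0
TWO_PI = 2.0 * math.pi


class SolverError(RuntimeError):
    """Non-convergence after the step-halving floor; carries the state."""

    def __init__(self, msg, t_days=None, psi_cm=None):
        super().__init__(msg)
        self.t_days = t_days
        self.psi_cm = psi_cm


@dataclass(frozen=True)
class Horizon:
    """One soil layer: depth range, retention curve, saturated conductivity."""

    z_top: float
    z_bot: float
    retention: RetentionParams
    K_s: float  # cm d^-1
    tortuosity: float = 0.5


@dataclass
class Scenario:
    """Full specification of a synthetic run; ``seed`` fixes all randomness."""

    name: str
    duration_days: int
    horizons: Sequence[Horizon]
    rld: Callable[[np.ndarray], np.ndarray] | float  # cm cm^-3 vs depth
    kr: Callable[[np.ndarray], np.ndarray] | float  # cm^2 d^-1 MPa^-1 vs depth
    psi0_mpa: tuple[float, float] = (-0.8, 0.0)  # psi0 = c0 + c1 * psi (MPa)
    demand_cm_per_day: float = 0.3
    demand_jitter_rel: float = 0.0
    lambda_max: float = 1.0
    day_start_hour: float = 6.0
    day_end_hour: float = 20.0
    rain_events: tuple = ()  # (start_day, amount_cm, duration_days)
    initial_psi_kpa: float | np.ndarray = -10.0
    bottom_bc: str = "free_drainage"  # or "no_flux"
    depth_cm: float = 60.0
    dz_cm: float = 1.0
    start: str = "2022-04-01"
    seed: int = 0
    sensor_depths: tuple = (15.0, 30.0, 45.0)
    interval_minutes: int = 15
    noise_sigma: float = 0.002
    picard_tol_theta: float = 1e-9
    picard_stall_theta: float = 1e-5  # acceptance bound for front chatter
    picard_max_iter: int = 40
    min_dt_days: float = 1e-6

    def grid(self) -> np.ndarray:
        """Cell-centre depths (cm)."""
        n = int(round(self.depth_cm / self.dz_cm))
        return (np.arange(n) + 0.5) * self.dz_cm

    def refined(self, factor: int = 2) -> "Scenario":
        """Same physics on a grid/step refined by ``factor`` (convergence checks)."""
        return replace(
            self,
            dz_cm=self.dz_cm / factor,
            interval_minutes=self.interval_minutes / factor,
        )


class _SoilProps:
    """Per-cell van Genuchten-Mualem parameter arrays (head in cm)."""

    def __init__(self, scenario: Scenario):
        z = scenario.grid()
        n = z.size
        self.theta_r = np.empty(n)
        self.theta_s = np.empty(n)
        self.a_cm = np.empty(n)
        self.n_vg = np.empty(n)
        self.K_s = np.empty(n)
        self.tort = np.empty(n)
        assigned = np.zeros(n, dtype=bool)
        for h in scenario.horizons:
            m = (z >= h.z_top) & (z < h.z_bot)
            self.theta_r[m] = h.retention.theta_r
            self.theta_s[m] = h.retention.theta_s
            self.a_cm[m] = h.retention.a_vg / CM_HEAD_PER_KPA
            self.n_vg[m] = h.retention.n
            self.K_s[m] = h.K_s
            self.tort[m] = h.tortuosity
            assigned |= m
        if not assigned.all():
            raise ValueError("horizons do not cover the whole grid")
        self.m_vg = 1.0 - 1.0 / self.n_vg

    def theta(self, psi_cm):
        se = self.sat(psi_cm)
        return self.theta_r + (self.theta_s - self.theta_r) * se

    def sat(self, psi_cm):
        apn = (self.a_cm * np.maximum(-psi_cm, 0.0)) ** self.n_vg
        return (1.0 + apn) ** (-self.m_vg)

    def capacity(self, psi_cm):
        """d(theta)/d(psi), per cm of head; 0 at saturation."""
        absp = np.maximum(-psi_cm, 0.0)
        apn = (self.a_cm * absp) ** self.n_vg
        c = (
            (self.theta_s - self.theta_r)
            * self.m_vg
            * self.n_vg
            * self.a_cm
            * (self.a_cm * absp) ** (self.n_vg - 1.0)
            * (1.0 + apn) ** (-self.m_vg - 1.0)
        )
        return np.where(psi_cm >= 0.0, 0.0, c)

    def K(self, psi_cm):
        se = np.clip(self.sat(psi_cm), 1e-12, 1.0)
        term = 1.0 - (1.0 - se ** (1.0 / self.m_vg)) ** self.m_vg
        return self.K_s * se**self.tort * term**2

    def psi(self, theta):
        th = np.clip(theta, self.theta_r + 1e-12, self.theta_s)
        se = (th - self.theta_r) / (self.theta_s - self.theta_r)
        with np.errstate(divide="ignore"):
            absp = (se ** (-1.0 / self.m_vg) - 1.0) ** (1.0 / self.n_vg) / self.a_cm
        return -absp


@dataclass
class SimulationResult:
    """Full ground-truth state of one run.

    ``theta``/``psi_kpa`` are instantaneous states at ``times`` (nt, nz);
    ``sink``, ``flux_top``, ``flux_bottom``, ``residual`` are per output
    interval (nt-1, ...), with sink and fluxes as mean rates over the
    interval and residual the water-budget closure error in cm.
    """

    scenario: Scenario
    times: pd.DatetimeIndex
    z: np.ndarray
    theta: np.ndarray
    psi_kpa: np.ndarray
    sink: np.ndarray
    flux_top: np.ndarray
    flux_bottom: np.ndarray
    residual: np.ndarray
    lambda_daily: np.ndarray
    kr_cells: np.ndarray
    rld_cells: np.ndarray

    @property
    def storage(self) -> np.ndarray:
        """Profile water storage (cm) at each output time."""
        return self.theta.sum(axis=1) * self.scenario.dz_cm

    def _interp_cols(self, arr, depth):
        return np.array([np.interp(depth, self.z, row) for row in arr])

    def theta_at_depth(self, depth: float) -> np.ndarray:
        return self._interp_cols(self.theta, depth)

    def psi_mpa_at_depth(self, depth: float) -> np.ndarray:
        return self._interp_cols(self.psi_kpa, depth) / 1000.0

    def sink_at_depth(self, depth: float) -> np.ndarray:
        return self._interp_cols(self.sink, depth)

    def daytime_mean_sink(self, depth: float, date) -> float:
        """True mean sink rate (d^-1) at a depth over one day's diurnal window."""
        day = pd.Timestamp(date).normalize()
        t1 = day + pd.Timedelta(hours=self.scenario.day_start_hour)
        t2 = day + pd.Timedelta(hours=self.scenario.day_end_hour)
        starts = self.times[:-1]
        m = (starts >= t1) & (starts < t2)
        if not m.any():
            raise ValueError(f"no output intervals inside daytime of {date}")
        return float(self.sink_at_depth(depth)[m].mean())

    def kr_effective(self, depth: float, day_index: int) -> float:
        """Prescribed-times-multiplier permeability at a depth on one day."""
        kr = float(np.interp(depth, self.z, self.kr_cells))
        return kr * float(self.lambda_daily[day_index])


def _rain_rate(events, t_day: float) -> float:
    rate = 0.0
    for start, amount, dur in events:
        if start <= t_day < start + dur:
            rate += amount / dur
    return rate


def simulate(scenario: Scenario) -> SimulationResult:
    """Run the scenario; see the module docstring for the model."""
    sc = scenario
    props = _SoilProps(sc)
    z = sc.grid()
    nz = z.size
    dz = sc.dz_cm
    rld = (np.full(nz, float(sc.rld)) if np.isscalar(sc.rld) else np.asarray(sc.rld(z), float))
    kr = (np.full(nz, float(sc.kr)) if np.isscalar(sc.kr) else np.asarray(sc.kr(z), float))
    if np.any(rld < 0) or np.any(kr < 0):
        raise ValueError("root length density and permeability must be >= 0")
    c0, c1 = sc.psi0_mpa
    sink_coeff = TWO_PI * kr * rld  # d^-1 MPa^-1

    psi = np.asarray(
        np.broadcast_to(np.atleast_1d(sc.initial_psi_kpa) * CM_HEAD_PER_KPA, (nz,)),
        dtype=float,
    ).copy()
    if np.any(psi > 0):
        raise ValueError("initial matric potential must be <= 0")
    theta = props.theta(psi)

    dt_out = sc.interval_minutes / (24.0 * 60.0)
    n_out = int(round(sc.duration_days / dt_out))
    times = pd.date_range(
        sc.start, periods=n_out + 1, freq=pd.Timedelta(minutes=sc.interval_minutes)
    )
    f_day = (sc.day_end_hour - sc.day_start_hour) / 24.0
    rng = np.random.default_rng(sc.seed)
    n_days = int(math.ceil(sc.duration_days))
    jit = (
        np.exp(rng.normal(0.0, sc.demand_jitter_rel, n_days) - 0.5 * sc.demand_jitter_rel**2)
        if sc.demand_jitter_rel > 0
        else np.ones(n_days)
    )
    lambda_daily = np.zeros(n_days)

    out_theta = np.empty((n_out + 1, nz))
    out_psi = np.empty((n_out + 1, nz))
    out_sink = np.zeros((n_out, nz))
    out_qtop = np.zeros(n_out)
    out_qbot = np.zeros(n_out)
    out_resid = np.zeros(n_out)
    out_theta[0] = theta
    out_psi[0] = psi / CM_HEAD_PER_KPA

    def sink_rate(psi_cm, lam, daylight):
        if not daylight or lam == 0.0:
            return np.zeros(nz), np.zeros(nz)
        psi_mpa = psi_cm / CM_HEAD_PER_MPA
        drive = psi_mpa - (c0 + c1 * psi_mpa)
        pos = drive > 0
        s = np.where(pos, lam * sink_coeff * drive, 0.0)
        dsdpsi_cm = np.where(pos, lam * sink_coeff * (1.0 - c1) / CM_HEAD_PER_MPA, 0.0)
        return s, dsdpsi_cm

    def interface_fluxes(psi_cm, q_top):
        """Downward fluxes at the nz+1 cell interfaces (cm d^-1).

        Rain inflow is limited to the infiltration capacity of the top
        cell (the Darcy flux from a saturated surface, psi = 0, to the
        first cell centre); the excess is runoff.  ``top_limited`` marks
        when that limiter is active so the Jacobian can pick up the
        resulting psi-dependence of the boundary flux.
        """
        K = props.K(psi_cm)
        # upstream-weighted interface conductivity: stable and monotone
        # across sharp wetting fronts (arithmetic means make the Picard
        # iteration chatter there)
        grad = (psi_cm[1:] - psi_cm[:-1]) / dz - 1.0
        K_int = np.where(grad < 0.0, K[:-1], K[1:])
        q = np.empty(nz + 1)
        # ponded-infiltration capacity: Darcy flux from a saturated surface
        # (psi = 0, conductivity K_s) to the first cell centre
        infil_cap = props.K_s[0] * (1.0 - 2.0 * psi_cm[0] / dz)
        top_limited = q_top > infil_cap
        q[0] = min(q_top, infil_cap) if q_top > 0 else q_top
        q[1:-1] = -K_int * grad
        q[-1] = K[-1] if sc.bottom_bc == "free_drainage" else 0.0
        return q, K, K_int, top_limited

    def step(theta_n, psi_n, dt, t_day, lam):
        """One implicit step; returns (theta, psi, q, s) or None on failure."""
        t_mid = t_day + 0.5 * dt
        hour = (t_mid % 1.0) * 24.0
        daylight = sc.day_start_hour <= hour < sc.day_end_hour
        q_top = _rain_rate(sc.rain_events, t_mid)
        psi_it = psi_n.copy()
        omega = 1.0  # under-relaxation against Picard limit cycles
        prev_move = None
        converged = False
        psi_best, move_best, it_best = None, np.inf, 0
        for it in range(sc.picard_max_iter):
            q, K, K_int, top_limited = interface_fluxes(psi_it, q_top)
            s, dsdpsi = sink_rate(psi_it, lam, daylight)
            theta_it = props.theta(psi_it)
            F = (theta_it - theta_n) / dt - (q[:-1] - q[1:]) / dz + s
            if it > 0 and np.max(np.abs(F)) * dt < sc.picard_tol_theta:
                converged = True
                break
            C = np.maximum(props.capacity(psi_it), 1e-12)
            diag = C / dt + dsdpsi
            lower = np.zeros(nz)
            upper = np.zeros(nz)
            diag[:-1] += K_int / dz**2
            diag[1:] += K_int / dz**2
            upper[1:] = -K_int / dz**2
            lower[:-1] = -K_int / dz**2
            if top_limited:
                diag[0] += 2.0 * props.K_s[0] / dz**2
            ab = np.vstack([upper, diag, lower])
            dpsi = solve_banded((1, 1), ab, -F)
            # positive psi is allowed: a saturated block carries pore
            # pressure (theta, K, C are flat there), so infiltration can
            # route through it; the block solves a Laplace problem.
            psi_prev = psi_it
            psi_it = psi_it + omega * dpsi
            move = float(np.max(np.abs(C * (psi_it - psi_prev))))
            if move < move_best:
                psi_best, move_best, it_best = psi_it, move, it
            if prev_move is not None and move > prev_move:
                omega = max(0.5 * omega, 1.0 / 32.0)
            prev_move = move
            if move < sc.picard_tol_theta:
                converged = True
                break
            if it - it_best >= 8 and move_best < sc.picard_stall_theta:
                break  # chattering at a saturation front; take the best iterate
        if not converged and move_best < sc.picard_stall_theta:
            # saturation-front chatter: accept the best stalled iterate;
            # the conservative update closes the budget exactly anyway
            psi_it = psi_best
            converged = True
        if not converged:
            import os
            if os.environ.get("RZF_DEBUG"):
                print(f"DEBUG picard-fail dt={dt:.2e} t={t_day:.5f} resF={np.max(np.abs(F))*dt:.2e} move={prev_move:.2e} psi0={psi_it[0]:.5f} psi1={psi_it[1]:.5f} lim={top_limited}")
            return None
        # conservative finite-volume update from the converged fluxes/sink
        q, K, K_int, _ = interface_fluxes(psi_it, q_top)
        s, _ = sink_rate(psi_it, lam, daylight)
        theta_new = theta_n + dt * ((q[:-1] - q[1:]) / dz - s)
        if theta_new[0] > props.theta_s[0]:
            # top cell would over-saturate: excess rain becomes runoff
            excess = (theta_new[0] - props.theta_s[0]) * dz / dt
            q[0] -= excess
            theta_new[0] = props.theta_s[0]
        # saturation overshoot at a sharp wetting front is pushed to the
        # next cell down (the front advancing), which conserves water
        # exactly; at the bottom it leaves as extra drainage.  Large
        # overshoots force a smaller step instead.
        if np.any(theta_new > props.theta_s):
            if np.max(theta_new - props.theta_s) > 3.0 * sc.picard_stall_theta:
                return None
            for i in range(nz):
                excess = theta_new[i] - props.theta_s[i]
                if excess > 0:
                    theta_new[i] = props.theta_s[i]
                    if i + 1 < nz:
                        theta_new[i + 1] += excess
                    else:
                        q[-1] += excess * dz / dt
        if np.any(theta_new < props.theta_r + 1e-12):
            if np.max(props.theta_r + 1e-12 - theta_new) > 10.0 * sc.picard_tol_theta:
                return None
            theta_new = np.maximum(theta_new, props.theta_r + 1e-12)
        psi_new = props.psi(theta_new)
        return theta_new, psi_new, q, s

    t_day = 0.0
    current_day = -1
    for k in range(n_out):
        if int(t_day + 1e-9) != current_day:
            current_day = int(t_day + 1e-9)
            drive = psi / CM_HEAD_PER_MPA - (c0 + c1 * psi / CM_HEAD_PER_MPA)
            capacity = float(np.sum(sink_coeff * np.maximum(drive, 0.0)) * dz)
            demand_rate = sc.demand_cm_per_day * jit[current_day] / f_day
            lam = 0.0 if capacity <= 0 else min(sc.lambda_max, demand_rate / capacity)
            lambda_daily[current_day] = lam
        remaining = dt_out
        dt = dt_out
        acc_s = np.zeros(nz)
        acc_qtop = 0.0
        acc_qbot = 0.0
        theta_start = theta.copy()
        while remaining > 1e-12:
            dt = min(dt, remaining)
            res = step(theta, psi, dt, t_day, lam)
            if res is None:
                dt /= 2.0
                if dt < sc.min_dt_days:
                    raise SolverError(
                        f"no convergence at t = {t_day:.4f} d (dt floor reached)",
                        t_days=t_day,
                        psi_cm=psi,
                    )
                continue
            theta, psi, q, s = res
            acc_s += s * dt
            acc_qtop += q[0] * dt
            acc_qbot += q[-1] * dt
            t_day += dt
            remaining -= dt
            if dt < dt_out:
                dt *= 2.0
        out_theta[k + 1] = theta
        out_psi[k + 1] = psi / CM_HEAD_PER_KPA
        out_sink[k] = acc_s / dt_out
        out_qtop[k] = acc_qtop / dt_out
        out_qbot[k] = acc_qbot / dt_out
        d_storage = (theta - theta_start).sum() * dz
        out_resid[k] = d_storage - (acc_qtop - acc_qbot) + acc_s.sum() * dz

    return SimulationResult(
        scenario=sc,
        times=times,
        z=z,
        theta=out_theta,
        psi_kpa=out_psi,
        sink=out_sink,
        flux_top=out_qtop,
        flux_bottom=out_qbot,
        residual=out_resid,
        lambda_daily=lambda_daily,
        kr_cells=kr,
        rld_cells=rld,
    )


def sample_sensors(
    result: SimulationResult,
    depths=None,
    interval_minutes: int | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> MoistureSeries:
    """Virtual logger: theta interpolated to sensor depths + Gaussian noise.

    Defaults come from the scenario; the output interval must be a
    multiple of the simulation output interval.  Same seed -> identical
    series.
    """
    sc = result.scenario
    depths = tuple(depths) if depths is not None else sc.sensor_depths
    interval_minutes = interval_minutes or sc.interval_minutes
    sigma = sc.noise_sigma if noise_sigma is None else noise_sigma
    seed = sc.seed if seed is None else seed
    if max(depths) > result.z.max() or min(depths) < result.z.min():
        raise ValueError(f"sensor depths {depths} outside grid")
    stride = int(round(interval_minutes / sc.interval_minutes))
    if stride < 1 or not math.isclose(stride * sc.interval_minutes, interval_minutes):
        raise ValueError("sampling interval must be a multiple of the output interval")
    times = result.times[::stride]
    theta = result.theta[::stride]
    cols = {}
    rng = np.random.default_rng(seed)
    for d in depths:
        vals = np.array([np.interp(d, result.z, row) for row in theta])
        if sigma > 0:
            vals = vals + rng.normal(0.0, sigma, vals.size)
        cols[float(d)] = np.clip(vals, 0.0, 1.0)
    frame = pd.DataFrame(cols, index=times)
    frame.index.name = "timestamp"
    return MoistureSeries(
        data=frame,
        interval=pd.Timedelta(minutes=interval_minutes),
        meta={"scenario": sc.name, "noise_sigma": sigma, "seed": seed},
    )
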