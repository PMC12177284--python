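"""Water-release (retention) curves: the theta <-> psi bridge.

The soil water release curve links volumetric water content theta to matric
potential psi (<= 0 in unsaturated soil).  The van Genuchten form with the
Mualem constraint m = 1 - 1/n is used throughout:

    theta(psi) = theta_r + (theta_s - theta_r) * [1 + (a*|psi|)^n]^(-m)

with theta_r / theta_s the residual / saturated water contents (fractions),
``a`` the inverse air-entry scale (kPa^-1) and n > 1 a shape parameter.
Matric potential is stored as kPa <= 0 everywhere in this package; MPa is
used only at the root-hydraulics boundary (1 MPa = 1000 kPa).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit


class RetentionError(ValueError):
    """Raised for invalid retention-curve inputs or failed fits."""


@dataclass(frozen=True)
class RetentionParams:
    """van Genuchten parameters with m = 1 - 1/n fixed.

    Parameters
    ----------
    theta_r : float
        Residual volumetric water content (fraction).
    theta_s : float
        Saturated volumetric water content (fraction).
    a_vg : float
        Inverse air-entry scale (kPa^-1), > 0.
    n : float
        Shape parameter, > 1.
    """

    theta_r: float
    theta_s: float
    a_vg: float
    n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise RetentionError(
                f"need 0 <= theta_r < theta_s <= 1, got ({self.theta_r}, {self.theta_s})"
            )
        if self.a_vg <= 0:
            raise RetentionError(f"a_vg must be > 0, got {self.a_vg}")
        if self.n <= 1:
            raise RetentionError(f"n must be > 1, got {self.n}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RetentionParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class RetentionFit:
    """A fitted retention curve plus least-squares diagnostics."""

    params: RetentionParams
    rmse: float
    covariance: np.ndarray  # 4x4, order (theta_r, theta_s, a_vg, n)
    n_obs: int


def psi_to_theta(psi, params: RetentionParams):
    """Water content at matric potential ``psi`` (kPa, <= 0).

    psi = 0 returns theta_s; theta decreases monotonically to theta_r
    as psi -> -inf.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise RetentionError("matric potential must be <= 0 kPa")
    se = (1.0 + (params.a_vg * np.abs(psi)) ** params.n) ** (-params.m)
    out = params.theta_r + (params.theta_s - params.theta_r) * se
    return out if out.ndim else float(out)


def theta_to_psi(theta, params: RetentionParams, clamp_saturated: bool = True):
    """Closed-form inverse of :func:`psi_to_theta` on (theta_r, theta_s].

    theta above theta_s is clamped to saturation (psi = 0) when
    ``clamp_saturated``; theta <= theta_r is out of range (the potential is
    unbounded below) and raises.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= params.theta_r):
        raise RetentionError(
            f"theta <= theta_r ({params.theta_r}): matric potential unbounded"
        )
    if np.any(theta > params.theta_s):
        if not clamp_saturated:
            raise RetentionError(f"theta above saturation ({params.theta_s})")
        theta = np.minimum(theta, params.theta_s)
    se = (theta - params.theta_r) / (params.theta_s - params.theta_r)
    # |psi| = (Se^(-1/m) - 1)^(1/n) / a ; exact inverse of the closed form
    with np.errstate(divide="ignore"):
        abs_psi = (se ** (-1.0 / params.m) - 1.0) ** (1.0 / params.n) / params.a_vg
    out = -abs_psi
    return out if out.ndim else float(out)


def water_capacity(psi, params: RetentionParams):
    """Specific water capacity C = d(theta)/d(psi) (kPa^-1) at psi <= 0."""
    psi = np.asarray(psi, dtype=float)
    apn = (params.a_vg * np.abs(psi)) ** params.n
    dtheta = params.theta_s - params.theta_r
    with np.errstate(invalid="ignore"):
        c = (
            dtheta
            * params.m
            * params.n
            * params.a_vg
            * (params.a_vg * np.abs(psi)) ** (params.n - 1.0)
            * (1.0 + apn) ** (-params.m - 1.0)
        )
    c = np.where(psi >= 0, 0.0, c)
    return c if c.ndim else float(c)


def _vg_model(psi, theta_r, theta_s, a_vg, n):
    m = 1.0 - 1.0 / n
    return theta_r + (theta_s - theta_r) * (1.0 + (a_vg * np.abs(psi)) ** n) ** (-m)


def fit_retention(psi_kpa, theta, p0: RetentionParams | None = None) -> RetentionFit:
    """Least-squares van Genuchten fit to (psi, theta) pairs.

    Parameters
    ----------
    psi_kpa : array-like
        Matric potentials, kPa, all <= 0. At least 5 pairs spanning at
        least one decade of |psi|.
    theta : array-like
        Observed water contents (fractions).
    p0 : RetentionParams, optional
        Initial guess; defaults to theta_s = max theta, theta_r = 0.5 min
        theta, a = 1/median|psi|, n = 1.5.

    Raises
    ------
    RetentionError
        On psi > 0, too few points, degenerate (constant) theta, or
        non-convergence.
    """
    psi = np.asarray(psi_kpa, dtype=float)
    th = np.asarray(theta, dtype=float)
    if psi.shape != th.shape or psi.ndim != 1:
        raise RetentionError("psi and theta must be 1-d arrays of equal length")
    if np.any(psi > 0):
        bad = int(np.argmax(psi > 0))
        raise RetentionError(f"psi must be <= 0 kPa (pair {bad}: psi={psi[bad]})")
    if psi.size < 5:
        raise RetentionError(f"need >= 5 pairs, got {psi.size}")
    nz = np.abs(psi[psi < 0])
    if nz.size < 2 or nz.max() / nz.min() < 10.0:
        raise RetentionError("|psi| must span at least one decade")
    if np.ptp(th) < 1e-12:
        raise RetentionError("degenerate input: theta has zero span")

    if p0 is None:
        guess = [0.5 * th.min(), th.max(), 1.0 / np.median(nz), 1.5]
    else:
        guess = [p0.theta_r, p0.theta_s, p0.a_vg, p0.n]
    lo = [0.0, 0.0, 1e-8, 1.0 + 1e-6]
    hi = [1.0, 1.0, 1e3, 12.0]
    guess = np.clip(guess, lo, hi)
    try:
        popt, pcov = curve_fit(
            _vg_model, psi, th, p0=guess, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RetentionError(f"retention fit did not converge: {exc}") from exc
    params = RetentionParams(*[float(v) for v in popt])
    resid = _vg_model(psi, *popt) - th
    return RetentionFit(
        params=params,
        rmse=float(np.sqrt(np.mean(resid**2))),
        covariance=pcov,
        n_obs=int(psi.size),
    )
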