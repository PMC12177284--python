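"""Root-side hydraulics: root length dynamics, core-break conversion, and
inversion of radial root water permeability k_r and root water potential psi0.

The volume-averaged uptake law for the roots in a soil layer is

    Q = 2*pi * k_r * L * (psi - psi0)

with Q the uptake rate per soil volume (d^-1), L root length density
(cm cm^-3), psi soil matric potential and psi0 the effective root water
potential (both MPa), and k_r the volume-average radial root water
permeability (cm^2 d^-1 MPa^-1).  k_r absorbs the per-segment geometry
factor ln(R_i/r_i); individual-segment permeabilities are not observable
from field data and are not represented here.

Given a fitted uptake-vs-potential curve s(psi) for one depth, a local
linearization over a small step dpsi yields both parameters:

    2*pi*k_r*L = [s(psi + dpsi) - s(psi)] / dpsi
    psi0       = psi - s(psi) * dpsi / [s(psi + dpsi) - s(psi)]

which is exact whenever s is linear in psi.  When psi0 is known (for
subsoil layers it is transferred from the topsoil psi0-psi relation,
assumed depth-invariant), k_r follows directly from one point:

    k_r = s / (2*pi * L * (psi - psi0))
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as date_t

import numpy as np

#: 1 cm d^-1 in m s^-1 (exact: 0.01 / 86400)
CM_PER_DAY_TO_M_PER_S = 0.01 / 86400.0


class InversionError(ValueError):
    """Singular or inconsistent permeability inversion."""


@dataclass(frozen=True)
class RootLayer:
    """Root population of one soil layer.

    L_m is root length density measured (destructively) at date t_m, the
    end of the observation period; alpha (d^-1) extrapolates L back in
    time; R (cm) is the representative root radius used only for the
    k_R = k_r/R conversion; stele_ratio (R/r >= 1) is metadata.
    """

    depth: float
    L_m: float
    t_m: date_t
    alpha: float = 0.0
    R: float = 0.015
    stele_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.L_m <= 0:
            raise ValueError(f"L_m must be > 0, got {self.L_m}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")


@dataclass(frozen=True)
class PermeabilityPoint:
    psi: float  # MPa, <= 0
    k_r: float  # cm^2 d^-1 MPa^-1
    psi0: float  # MPa
    depth: float
    growth_scenario: float = 0.0  # the alpha used
    group: str = "pooled"  # before_rain | after_rain | pooled
    flagged: bool = False  # sign-floored k_r or extrapolated psi0


def root_length_at(t: date_t, layer: RootLayer, sign_convention: str = "printed") -> float:
    """Root length density at an earlier date t (t <= t_m), cm cm^-3.

    Two conventions for the backward extrapolation from the measured L_m:

    * "printed":  L(t) = L_m * (alpha*(t_m - t) + 1) — root length density
      *larger* before the measurement, declining toward it.  This is the
      literal extrapolation form adopted here as the default; note it makes
      alpha act as a decline-toward-measurement rate even though alpha is
      conventionally called a growth rate.
    * "growth":   L(t) = L_m * (1 - alpha*(t_m - t)), floored at 0.05*L_m —
      roots actually growing toward t_m.

    The two bracket L_m symmetrically; alpha = 0 gives L = L_m always.
    """
    if t > layer.t_m:
        raise ValueError(f"cannot extrapolate forward of t_m ({layer.t_m})")
    dt = (layer.t_m - t).days + ((layer.t_m - t).seconds / 86400.0)
    if sign_convention == "printed":
        return layer.L_m * (layer.alpha * dt + 1.0)
    if sign_convention == "growth":
        return max(layer.L_m * (1.0 - layer.alpha * dt), 0.05 * layer.L_m)
    raise ValueError(f"unknown sign_convention {sign_convention!r}")


def rld_from_core_break(
    face_counts,
    core_diameter_cm: float = 5.0,
    orientation_factor: float = 1.0,
) -> float:
    """Root length density from core-break face counts (cm cm^-3).

    ``face_counts`` holds, per rotation (three, 120 deg apart), the summed
    count over both faces of the breakpoint.  Each through-running root
    appears on both faces, so the both-sides sum is halved before
    normalizing by the core cross-section.  Under the parallel-roots
    assumption the orientation factor is 1 (set 2 for isotropic roots).
    """
    counts = np.asarray(face_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty face counts")
    if np.any(counts < 0):
        raise ValueError("negative root counts")
    if core_diameter_cm <= 0:
        raise ValueError("core diameter must be > 0")
    n_roots = float(np.mean(counts)) / 2.0
    area = math.pi * (core_diameter_cm / 2.0) ** 2
    return orientation_factor * n_roots / area


def invert_kr_psi0(
    s_of_psi,
    psi: float,
    dpsi: float | None = None,
    L: float = 1.0,
) -> tuple[float, float, bool]:
    """Local-linearization inversion for (k_r, psi0) at matric potential psi.

    Parameters
    ----------
    s_of_psi : callable
        Fitted uptake curve s(psi) for the depth, d^-1 vs MPa.
    psi : float
        Evaluation potential (MPa, <= 0).
    dpsi : float, optional
        Linearization step (MPa); defaults to -5% of |psi| (the step is
        taken toward drier soil).
    L : float
        Root length density (cm cm^-3), > 0.

    Returns
    -------
    (k_r, psi0, flagged) : k_r in cm^2 d^-1 MPa^-1; ``flagged`` is True
    when a negative slope forced the k_r >= 0 floor.

    Raises
    ------
    InversionError
        If the local slope is zero (s constant in psi).
    """
    if L <= 0:
        raise ValueError(f"L must be > 0, got {L}")
    if dpsi is None:
        dpsi = -0.05 * abs(psi)
    if dpsi == 0:
        raise ValueError("dpsi must be nonzero")
    s0 = float(s_of_psi(psi))
    s1 = float(s_of_psi(psi + dpsi))
    ds = s1 - s0
    if ds == 0.0:
        raise InversionError(f"s(psi) locally constant at psi={psi}: singular inversion")
    slope = ds / dpsi
    psi0 = psi - s0 * dpsi / ds
    k_r = slope / (2.0 * math.pi * L)
    flagged = False
    if k_r < 0:
        k_r, flagged = 0.0, True
    return k_r, psi0, flagged


def kr_given_psi0(s: float, psi: float, psi0: float, L: float) -> float:
    """k_r from one uptake observation when psi0 is known.

    k_r = s / (2*pi*L*(psi - psi0)); requires psi > psi0 whenever s > 0
    (water cannot flow into roots against the potential gradient).
    """
    if L <= 0:
        raise ValueError(f"L must be > 0, got {L}")
    if s == 0:
        return 0.0
    if psi <= psi0:
        raise InversionError(
            f"psi ({psi}) <= psi0 ({psi0}) with s = {s} > 0: inconsistent"
        )
    return s / (2.0 * math.pi * L * (psi - psi0))


def transfer_psi0_to_subsoil(topsoil_relation, subsoil_psi):
    """Evaluate the topsoil psi0(psi) relation at subsoil potentials.

    The relation (anchor points or a callable) is assumed independent of
    soil depth.  Anchors are linearly interpolated; evaluations outside
    the anchored psi range are flagged as extrapolated (linear-edge
    extension).

    Returns (psi0, extrapolated_flag) arrays matching ``subsoil_psi``.
    """
    psi = np.atleast_1d(np.asarray(subsoil_psi, dtype=float))
    if callable(topsoil_relation):
        out = np.asarray([float(topsoil_relation(p)) for p in psi])
        flags = np.zeros(psi.shape, dtype=bool)
        return (out[0], False) if np.isscalar(subsoil_psi) or psi.size == 1 else (out, flags)
    anchors = np.asarray(topsoil_relation, dtype=float)
    if anchors.size == 0:
        raise ValueError("empty topsoil psi0 relation")
    anchors = anchors[np.argsort(anchors[:, 0])]
    xa, ya = anchors[:, 0], anchors[:, 1]
    out = np.interp(psi, xa, ya)
    flags = (psi < xa[0]) | (psi > xa[-1])
    # linear-edge extension beyond the anchored range, flagged
    if anchors.shape[0] >= 2:
        lo_slope = (ya[1] - ya[0]) / (xa[1] - xa[0])
        hi_slope = (ya[-1] - ya[-2]) / (xa[-1] - xa[-2])
        out = np.where(psi < xa[0], ya[0] + lo_slope * (psi - xa[0]), out)
        out = np.where(psi > xa[-1], ya[-1] + hi_slope * (psi - xa[-1]), out)
    if np.isscalar(subsoil_psi):
        return float(out[0]), bool(flags[0])
    return out, flags


def kr_to_kR(k_r: float, R: float) -> tuple[float, float]:
    """Permeability -> surface-area-based hydraulic conductivity, k_R = k_r/R.

    Returns (k_R in cm d^-1 MPa^-1, k_R in m s^-1 MPa^-1).  R is the
    representative root radius in cm.
    """
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    kR_cmd = k_r / R
    return kR_cmd, kR_cmd * CM_PER_DAY_TO_M_PER_S
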