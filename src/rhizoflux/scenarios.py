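"""Named reference scenarios for validation and acceptance runs.

The shapes emulate the study system this package targets: a silty clay
loam profile instrumented at 15/30/45 cm, logged every 15 min over a
spring drying season with occasional rainfall, vegetated by a crop whose
roots thin roughly exponentially with depth.  Soil hydraulic parameters
are the Carsel & Parrish class values for silty clay loam; the uptake-law
parameters sit inside the range this method reports for wheat topsoil.
"""

from __future__ import annotations

import numpy as np

from .retention import RetentionParams
from .simulate import Horizon, Scenario

#: Carsel & Parrish silty clay loam (a converted from cm^-1 to kPa^-1)
SILTY_CLAY_LOAM = RetentionParams(theta_r=0.089, theta_s=0.43, a_vg=0.10197, n=1.23)
SCL_KSAT = 1.68  # cm d^-1


def exponential_roots(L0: float = 6.0, z_scale: float = 25.0):
    """Root length density profile L(z) = L0 * exp(-z/z_scale), cm cm^-3."""

    def rld(z):
        return L0 * np.exp(-np.asarray(z, float) / z_scale)

    return rld


def _horizons(K_s: float) -> list[Horizon]:
    return [Horizon(z_top=0.0, z_bot=60.0, retention=SILTY_CLAY_LOAM, K_s=K_s)]


def reference_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """The standard scenario set, fully seeded.

    * ``no-flow``       — zero soil conductivity: the diel estimator is exact.
    * ``baseline-drying`` — 30-day rain-free dry-down, supply-limited uptake
      (demand above root capacity, multiplier capped at 1), constant k_r and
      psi0: the parameter-recovery workhorse.
    * ``two-rains``     — 90 days, demand-tracking uptake with jitter, rain
      pulses on days 5 and 65 (the before/after-rainfall grouping shape).
    * ``depth-invariant-psi0`` — psi0 prescribed as the same linear function
      of local psi at every depth, for the subsoil-transfer validation.
    """
    common = dict(
        rld=exponential_roots(),
        day_start_hour=6.0,
        day_end_hour=20.0,
        initial_psi_kpa=-8.0,
        sensor_depths=(15.0, 30.0, 45.0),
        interval_minutes=15,
        noise_sigma=0.002,
    )
    return {
        "no-flow": Scenario(
            name="no-flow",
            duration_days=10,
            horizons=_horizons(0.0),
            kr=0.0012,
            psi0_mpa=(-0.8, 0.0),
            demand_cm_per_day=0.35,
            lambda_max=1.0,
            seed=seed,
            **common,
        ),
        "baseline-drying": Scenario(
            name="baseline-drying",
            duration_days=30,
            horizons=_horizons(SCL_KSAT),
            kr=0.0015,
            psi0_mpa=(-0.8, 0.0),
            demand_cm_per_day=0.65,
            demand_jitter_rel=0.0,
            lambda_max=1.0,
            seed=seed + 1,
            **common,
        ),
        "two-rains": Scenario(
            name="two-rains",
            duration_days=90,
            horizons=_horizons(SCL_KSAT),
            kr=0.0025,
            psi0_mpa=(-0.8, 0.0),
            demand_cm_per_day=0.12,
            demand_jitter_rel=0.15,
            lambda_max=4.0,
            rain_events=((5.0, 2.0, 1.0), (65.0, 2.0, 1.0)),
            seed=seed + 2,
            **common,
        ),
        "depth-invariant-psi0": Scenario(
            name="depth-invariant-psi0",
            duration_days=30,
            horizons=_horizons(SCL_KSAT),
            kr=0.0015,
            psi0_mpa=(-0.5, 0.1),
            demand_cm_per_day=0.40,
            lambda_max=1.0,
            seed=seed + 3,
            **common,
        ),
    }
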