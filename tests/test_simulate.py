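"""Soil-water simulator: conservation, boundary behaviour, virtual sensors."""

import numpy as np
import pandas as pd
import pytest

from rhizoflux.retention import RetentionParams, psi_to_theta
from rhizoflux.scenarios import SILTY_CLAY_LOAM, exponential_roots, reference_scenarios
from rhizoflux.simulate import Horizon, Scenario, sample_sensors, simulate


def mini_scenario(**overrides):
    base = dict(
        name="mini",
        duration_days=2,
        horizons=[Horizon(0.0, 60.0, SILTY_CLAY_LOAM, K_s=1.68)],
        rld=exponential_roots(),
        kr=0.0015,
        psi0_mpa=(-0.8, 0.0),
        demand_cm_per_day=0.6,
        lambda_max=1.0,
        initial_psi_kpa=-8.0,
        seed=0,
    )
    base.update(overrides)
    return Scenario(**base)


class TestStorageOnlyBalance:
    def test_zero_conductivity_is_pure_storage_change(self):
        res = simulate(mini_scenario(horizons=[Horizon(0.0, 60.0, SILTY_CLAY_LOAM, K_s=0.0)]))
        dt = 15.0 / (24 * 60)
        d_theta = res.theta[-1] - res.theta[0]
        extracted = -res.sink.sum(axis=0) * dt
        np.testing.assert_allclose(d_theta, extracted, atol=1e-12)
        assert np.all(res.flux_top == 0) and np.all(res.flux_bottom == 0)

    def test_sink_only_during_diurnal_window(self, noflow_result):
        hours = noflow_result.times[:-1].hour
        night = (hours < 6) | (hours >= 20)
        assert np.all(noflow_result.sink[night] == 0)
        day_total = noflow_result.sink[~night].sum()
        assert day_total > 0


class TestEquilibrium:
    def test_hydrostatic_profile_is_steady_without_sink_or_drainage(self):
        z = (np.arange(60) + 0.5) * 1.0
        from rhizoflux.simulate import CM_HEAD_PER_KPA

        # total head constant: psi_cm = psi_bottom - (z_bottom - z)
        psi_cm = -300.0 - (59.5 - z)
        res = simulate(
            mini_scenario(
                kr=0.0,
                rld=0.0,
                initial_psi_kpa=psi_cm / CM_HEAD_PER_KPA,
                bottom_bc="no_flux",
                duration_days=1,
            )
        )
        assert np.max(np.abs(res.theta[-1] - res.theta[0])) < 1e-9


class TestConservation:
    @pytest.mark.parametrize("name", ["no-flow", "baseline-drying", "depth-invariant-psi0"])
    def test_reference_scenarios_close_water_budget(self, scenarios, request, name):
        fixture = {
            "no-flow": "noflow_result",
            "baseline-drying": "baseline_result",
            "depth-invariant-psi0": "depth_invariant_result",
        }[name]
        res = request.getfixturevalue(fixture)
        assert np.abs(res.residual).sum() <= 1e-6 * res.storage[0]

    def test_rainfall_scenario_closes_water_budget(self, two_rains_result):
        res = two_rains_result
        assert np.abs(res.residual).sum() <= 1e-6 * res.storage[0]

    def test_theta_stays_above_uptake_limit(self, baseline_result):
        # the sink shuts off at psi0, so theta can never be drawn below
        # the water content in equilibrium with the root water potential
        sc = baseline_result.scenario
        psi0_kpa = sc.psi0_mpa[0] * 1000.0
        theta_floor = psi_to_theta(psi0_kpa, SILTY_CLAY_LOAM)
        # free drainage (not the sink) may nudge theta marginally below
        assert baseline_result.theta.min() >= theta_floor - 1e-5

    def test_theta_within_physical_bounds(self, two_rains_result):
        assert two_rains_result.theta.max() <= SILTY_CLAY_LOAM.theta_s + 1e-9
        assert two_rains_result.theta.min() > SILTY_CLAY_LOAM.theta_r


class TestGridConvergence:
    def test_day_integrated_sink_stable_under_refinement(self):
        coarse = simulate(mini_scenario())
        fine = simulate(mini_scenario().refined(2))
        dt_c = 15.0 / (24 * 60)
        dt_f = dt_c / 2
        for depth in (15.0, 30.0, 45.0):
            s_c = coarse.sink_at_depth(depth).sum() * dt_c
            s_f = fine.sink_at_depth(depth).sum() * dt_f
            assert s_f == pytest.approx(s_c, rel=0.01)


class TestSensors:
    def test_noiseless_sampling_matches_state(self, noflow_result):
        series = sample_sensors(noflow_result, noise_sigma=0.0)
        for depth in (15.0, 30.0, 45.0):
            np.testing.assert_allclose(
                series.data[depth].to_numpy(),
                noflow_result.theta_at_depth(depth),
                atol=1e-12,
            )

    def test_same_seed_identical_series(self, noflow_result):
        a = sample_sensors(noflow_result, seed=9)
        b = sample_sensors(noflow_result, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = sample_sensors(noflow_result, seed=10)
        assert not a.data.equals(c.data)

    def test_noise_amplitude_calibrated(self, two_rains_result):
        clean = sample_sensors(two_rains_result, noise_sigma=0.0)
        noisy = sample_sensors(two_rains_result, noise_sigma=0.002, seed=3)
        resid = (noisy.data - clean.data).to_numpy().ravel()
        assert resid.size > 1e4
        assert np.std(resid) == pytest.approx(0.002, rel=0.05)

    def test_depth_outside_grid_rejected(self, noflow_result):
        with pytest.raises(ValueError):
            sample_sensors(noflow_result, depths=(15.0, 120.0))


class TestScenarioSet:
    def test_reference_set_complete_and_seeded(self):
        scens = reference_scenarios(seed=5)
        assert {"no-flow", "baseline-drying", "two-rains", "depth-invariant-psi0"} <= set(scens)
        assert all(s.seed is not None for s in scens.values())

    def test_baseline_topsoil_dries_monotonically(self, baseline_result):
        daily = baseline_result.theta_at_depth(15.0)[:: 96]
        assert np.all(np.diff(daily) < 0)
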