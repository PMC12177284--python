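"""Root length dynamics, core-break conversion, permeability inversion."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizoflux.hydraulics import (
    InversionError,
    RootLayer,
    invert_kr_psi0,
    kr_given_psi0,
    kr_to_kR,
    rld_from_core_break,
    root_length_at,
    transfer_psi0_to_subsoil,
)

T_M = date(2022, 6, 30)


class TestRootLength:
    def test_no_growth_returns_measured_density(self):
        layer = RootLayer(depth=15, L_m=2.0, t_m=T_M, alpha=0.0)
        assert root_length_at(date(2022, 4, 1), layer) == 2.0

    def test_printed_convention_direct_substitution(self):
        layer = RootLayer(depth=15, L_m=2.0, t_m=T_M, alpha=0.002)
        t = date(2022, 5, 11)  # 50 days before t_m
        assert root_length_at(t, layer, "printed") == pytest.approx(2.0 * 1.10)

    def test_conventions_bracket_symmetrically(self):
        layer = RootLayer(depth=15, L_m=2.0, t_m=T_M, alpha=0.002)
        t = date(2022, 5, 1)
        lo = root_length_at(t, layer, "growth")
        hi = root_length_at(t, layer, "printed")
        assert (lo + hi) / 2 == pytest.approx(layer.L_m)

    def test_forward_extrapolation_rejected(self):
        layer = RootLayer(depth=15, L_m=2.0, t_m=T_M)
        with pytest.raises(ValueError):
            root_length_at(date(2022, 7, 1), layer)


class TestCoreBreak:
    def test_zero_counts_zero_density(self):
        assert rld_from_core_break([0, 0, 0]) == 0.0

    def test_hand_computation(self):
        # both-sides sums (40, 40, 40), 5 cm core: N = 20, area 19.635 cm^2
        rld = rld_from_core_break([40, 40, 40], core_diameter_cm=5.0)
        assert rld == pytest.approx(20.0 / (math.pi * 6.25), rel=1e-12)
        assert rld == pytest.approx(1.019, abs=5e-4)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            rld_from_core_break([])

    def test_virtual_core_break_recovers_constructed_density(self):
        # vertical line-roots scattered uniformly; a root crossing the
        # break plane inside the core shows on both faces
        rng = np.random.default_rng(12)
        true_density = 2.0  # cm cm^-3 (vertical roots: count per area)
        side = 40.0
        radius = 2.5
        estimates = []
        for _ in range(50):
            n_roots = rng.poisson(true_density * side * side)
            xy = rng.uniform(0, side, (n_roots, 2))
            inside = ((xy - side / 2) ** 2).sum(axis=1) <= radius**2
            both_sides = 2 * int(inside.sum())
            estimates.append(
                rld_from_core_break([both_sides] * 3, core_diameter_cm=2 * radius)
            )
        assert np.mean(estimates) == pytest.approx(true_density, rel=0.10)


class TestInversion:
    def make_linear(self, k_r, psi0, L):
        return lambda psi: 2 * math.pi * k_r * L * (psi - psi0)

    def test_closed_form_self_inversion(self):
        s = self.make_linear(0.004, -0.9, 2.0)
        k_r, psi0, flagged = invert_kr_psi0(s, psi=-0.1, dpsi=-0.05, L=2.0)
        assert k_r == pytest.approx(0.004, rel=1e-12)
        assert psi0 == pytest.approx(-0.9, rel=1e-12)
        assert not flagged

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k_r=st.floats(1e-4, 0.05),
        psi0=st.floats(-2.0, -0.2),
        L=st.floats(0.1, 10.0),
        psi=st.floats(-0.19, -0.01),
        dpsi=st.floats(-0.2, 0.2).filter(lambda d: abs(d) > 1e-4),
    )
    def test_forward_inverse_closure_any_step(self, k_r, psi0, L, psi, dpsi):
        s = self.make_linear(k_r, psi0, L)
        got_k, got_psi0, _ = invert_kr_psi0(s, psi=psi, dpsi=dpsi, L=L)
        assert got_k == pytest.approx(k_r, rel=1e-9)
        assert got_psi0 == pytest.approx(psi0, rel=1e-9)

    def test_constant_curve_is_singular(self):
        with pytest.raises(InversionError):
            invert_kr_psi0(lambda psi: 0.02, psi=-0.1, dpsi=-0.01, L=1.0)

    def test_unit_rescaling_consistency(self):
        # all potentials in kPa instead of MPa: k_r comes out in per-kPa
        # units, smaller by exactly 1000
        s_mpa = self.make_linear(0.004, -0.9, 2.0)
        s_kpa = lambda psi_kpa: s_mpa(psi_kpa / 1000.0)
        k_mpa, psi0_mpa, _ = invert_kr_psi0(s_mpa, -0.1, -0.05, 2.0)
        k_kpa, psi0_kpa, _ = invert_kr_psi0(s_kpa, -100.0, -50.0, 2.0)
        assert k_kpa * 1000 == pytest.approx(k_mpa, rel=1e-9)
        assert psi0_kpa / 1000 == pytest.approx(psi0_mpa, rel=1e-9)


class TestKrGivenPsi0:
    def test_arithmetic_inverse_of_forward_law(self):
        assert kr_given_psi0(0.0402, -0.1, -0.9, 2.0) == pytest.approx(
            0.0402 / (2 * math.pi * 2.0 * 0.8), rel=1e-12
        )
        assert kr_given_psi0(0.0402, -0.1, -0.9, 2.0) == pytest.approx(0.004, abs=1e-5)

    def test_zero_uptake_zero_permeability(self):
        assert kr_given_psi0(0.0, -0.1, -0.9, 2.0) == 0.0

    def test_inconsistent_potentials_rejected(self):
        with pytest.raises(InversionError):
            kr_given_psi0(0.01, -1.0, -0.5, 2.0)

    def test_consistent_with_two_parameter_inversion(self):
        s = lambda psi: 2 * math.pi * 0.003 * 1.5 * (psi - (-0.7))
        k2, psi0, _ = invert_kr_psi0(s, -0.2, -0.02, 1.5)
        k1 = kr_given_psi0(s(-0.2), -0.2, psi0, 1.5)
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_growth_envelope_orders_permeability(self):
        # the same uptake attributed to more root length means lower k_r
        layer = RootLayer(depth=15, L_m=2.0, t_m=T_M, alpha=0.002)
        t = date(2022, 5, 1)
        L_grown = root_length_at(t, layer, "printed")
        L_static = layer.L_m
        k_static = kr_given_psi0(0.02, -0.1, -0.9, L_static)
        k_grown = kr_given_psi0(0.02, -0.1, -0.9, L_grown)
        assert L_grown > L_static
        assert k_grown < k_static


class TestPsi0Transfer:
    def test_anchor_node_is_exact(self):
        anchors = [(-0.4, -0.9), (-0.2, -0.7), (-0.05, -0.6)]
        psi0, extrap = transfer_psi0_to_subsoil(anchors, -0.2)
        assert psi0 == -0.7 and not extrap

    def test_linear_relation_evaluation(self):
        psi0, extrap = transfer_psi0_to_subsoil(lambda p: 1.5 * p - 0.4, -0.2)
        assert psi0 == pytest.approx(-0.7)

    def test_out_of_range_flagged(self):
        anchors = [(-0.4, -0.9), (-0.2, -0.7)]
        psi0, extrap = transfer_psi0_to_subsoil(anchors, -0.05)
        assert extrap
        assert psi0 == pytest.approx(-0.55)  # linear edge extension

    def test_empty_relation_rejected(self):
        with pytest.raises(ValueError):
            transfer_psi0_to_subsoil([], -0.1)


class TestUnitConversion:
    def test_reported_wheat_topsoil_range(self):
        _, lo = kr_to_kR(0.001, R=0.015)
        _, hi = kr_to_kR(0.007, R=0.015)
        assert lo == pytest.approx(7.7e-9, rel=0.01)
        assert hi == pytest.approx(5.4e-8, rel=0.01)

    def test_zero_permeability(self):
        assert kr_to_kR(0.0, R=0.015) == (0.0, 0.0)

    def test_dimensional_recomputation_with_stated_diameter(self):
        # 0.6 mm diameter -> R = 0.03 cm; independent unit chain:
        # (cm^2/d/MPa) / cm = cm/d/MPa; 1 cm/d = 0.01/86400 m/s
        k_cmd, k_si = kr_to_kR(0.001, R=0.03)
        assert k_cmd == pytest.approx(0.001 / 0.03, rel=1e-12)
        assert k_si == pytest.approx((0.001 / 0.03) * 0.01 / 86400, rel=1e-12)
        assert k_si == pytest.approx(3.9e-9, rel=0.02)  # factor ~2 below 7.7e-9
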