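"""Mechanics: kinematics, wall-stress laws and acoustoelastic moduli.

The moduli are validated against an independent finite-difference oracle:
numerical differentiation of the constrained Demiray–Fung energy
W~(l1, l2) = W(l1, l2, 1/(l1*l2)) plugged into the generic incremental-
modulus expressions (denominators l1^2 - l2^2).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lambpress import mechanics as mech
from lambpress.mechanics import (CompartmentGeometry, MaterialModel,
                                 demiray_fung_stress_difference,
                                 incremental_moduli, log_wall_pressure,
                                 moduli_from_pressure, pressure_from_volume,
                                 radius_from_volume,
                                 reference_volume_from_thickness,
                                 stretch_coefficients, stretches_from_volumes,
                                 thin_wall_pressure)

# ---------------------------------------------------------------- oracle


def constrained_energy(l1: float, l2: float, mu0: float, b: float) -> float:
    """Demiray–Fung energy with the third stretch eliminated by
    incompressibility (the oracle's only model knowledge)."""
    l3 = 1.0 / (l1 * l2)
    I1 = l1 * l1 + l2 * l2 + l3 * l3
    if b == 0.0:
        return 0.5 * mu0 * (I1 - 3.0)
    return mu0 / (2.0 * b) * (math.exp(b * (I1 - 3.0)) - 1.0)


def _fd_moduli_step(l1, l2, mu0, b, h):
    W = lambda a, c: constrained_energy(a, c, mu0, b)  # noqa: E731
    W1 = (W(l1 + h, l2) - W(l1 - h, l2)) / (2 * h)
    W2 = (W(l1, l2 + h) - W(l1, l2 - h)) / (2 * h)
    W11 = (W(l1 + h, l2) - 2 * W(l1, l2) + W(l1 - h, l2)) / h**2
    W22 = (W(l1, l2 + h) - 2 * W(l1, l2) + W(l1, l2 - h)) / h**2
    W12 = (W(l1 + h, l2 + h) - W(l1 + h, l2 - h)
           - W(l1 - h, l2 + h) + W(l1 - h, l2 - h)) / (4 * h**2)
    denom = l1**2 - l2**2
    alpha = l1**2 * (l1 * W1 - l2 * W2) / denom
    gamma = l2**2 * (l1 * W1 - l2 * W2) / denom
    beta2 = (l1**2 * W11 + l2**2 * W22 - 2 * l1 * l2 * W12
             - 2 * l1 * l2 * (l2 * W1 - l1 * W2) / denom)
    return np.array([alpha, gamma, beta2])


def fd_moduli(l1, l2, mu0, b, h=2e-4):
    """(alpha, gamma, 2beta) by Richardson-extrapolated central finite
    differences of the energy (O(h^4) truncation)."""
    coarse = _fd_moduli_step(l1, l2, mu0, b, h)
    fine = _fd_moduli_step(l1, l2, mu0, b, h / 2.0)
    return (4.0 * fine - coarse) / 3.0


def spherical_l2(l1: float) -> float:
    return l1 ** -2


# ----------------------------------------------------------- kinematics


class TestKinematics:
    def test_unit_sphere_radius(self):
        assert radius_from_volume(4.0 * math.pi / 3.0) == pytest.approx(1.0)

    def test_radius_inverts_sphere_volume(self):
        V = 268.0826e-6
        r = radius_from_volume(V)
        assert 4.0 / 3.0 * math.pi * r**3 == pytest.approx(V, rel=1e-12)
        assert r == pytest.approx(0.0400, abs=5e-4)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_volume_rejected(self, bad):
        with pytest.raises(ValueError):
            radius_from_volume(bad)

    def test_identity_deformation(self):
        d = stretches_from_volumes(2.0, 2.0)
        assert (d.lam1, d.lam2, d.I1) == (1.0, 1.0, 3.0)

    def test_octupled_volume(self):
        d = stretches_from_volumes(8.0, 1.0)
        assert d.lam1 == pytest.approx(2.0)
        assert d.lam2 == pytest.approx(0.25)
        assert d.lam3 == d.lam1

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_incompressibility_identity(self, V, V0):
        d = stretches_from_volumes(V, V0)
        assert d.lam1**2 * d.lam2 == pytest.approx(1.0, rel=1e-12)

    def test_reference_volume_from_thickness(self):
        assert reference_volume_from_thickness(1e-3, 1e-3, 5.0) == 5.0
        assert reference_volume_from_thickness(0.25e-3, 1e-3, 8.0) == \
            pytest.approx(1.0)

    @given(st.floats(0.2, 5.0), st.floats(0.2, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_thickness_round_trip(self, V, V0):
        h0 = 2.75e-3
        h = stretches_from_volumes(V, V0).lam2 * h0
        assert reference_volume_from_thickness(h, h0, V) == \
            pytest.approx(V0, rel=1e-12)


# ------------------------------------------------------ wall-stress laws


class TestPressureLaws:
    def test_zero_stress_zero_pressure(self):
        assert thin_wall_pressure(0.0, 1e-3, 0.04) == 0.0
        assert log_wall_pressure(0.0, 0.04, 0.041) == 0.0

    def test_thin_wall_arithmetic(self):
        # 10 kPa stress, 2.5 mm half-thickness, 40 mm radius -> 2.5 kPa
        assert thin_wall_pressure(10e3, 2.5e-3, 40e-3) == pytest.approx(2500.0)

    def test_log_law_equals_taylor_limit(self):
        t = 10e3
        a = 0.04
        P_log = log_wall_pressure(t, a, 1.01 * a)
        # thin-wall form with h = (b - a)/2
        P_thin = thin_wall_pressure(t, 0.005 * a, a)
        assert abs(P_log - P_thin) / P_log < 0.01

    def test_thin_wall_error_grows_with_thickness(self):
        t = 10e3
        a = 0.04
        ratios = np.linspace(1.001, 2.0, 40)
        rel = []
        for rho in ratios:
            P_log = log_wall_pressure(t, a, rho * a)
            P_thin = thin_wall_pressure(t, 0.5 * (rho - 1.0) * a, a)
            rel.append(abs(P_log - P_thin) / P_log)
        assert np.all(np.diff(rel) > 0)

    def test_outer_radius_smaller_than_inner_rejected(self):
        with pytest.raises(ValueError):
            log_wall_pressure(1.0, 0.05, 0.04)


# ------------------------------------------------- stress & moduli oracle


class TestDemirayFungStress:
    def test_zero_at_identity(self):
        d = stretches_from_volumes(1.0, 1.0)
        m = MaterialModel(mu0=10e3, b_stiff=5.0)
        assert demiray_fung_stress_difference(d, m).t_diff == 0.0

    def test_neo_hookean_reduction(self):
        l1 = 1.2
        d = stretches_from_volumes(l1**3, 1.0)
        m = MaterialModel(mu0=7e3, b_stiff=0.0)
        expect = 7e3 * (l1**2 - l1**-4)
        assert demiray_fung_stress_difference(d, m).t_diff == \
            pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("l1", [1.05, 1.2, 1.5])
    @pytest.mark.parametrize("b", [0.0, 1.0, 5.0])
    def test_matches_energy_derivative(self, l1, b):
        mu0 = 12e3
        d = stretches_from_volumes(l1**3, 1.0)
        got = demiray_fung_stress_difference(d, MaterialModel(mu0, b)).t_diff
        h = 1e-6
        W = lambda a, c: constrained_energy(a, c, mu0, b)  # noqa: E731
        l2 = spherical_l2(l1)
        W1 = (W(l1 + h, l2) - W(l1 - h, l2)) / (2 * h)
        W2 = (W(l1, l2 + h) - W(l1, l2 - h)) / (2 * h)
        assert got == pytest.approx(l1 * W1 - l2 * W2, rel=1e-6)

    def test_monotone_in_material_parameters(self):
        d = stretches_from_volumes(1.5, 1.0)
        base = demiray_fung_stress_difference(d, MaterialModel(5e3, 2.0)).t_diff
        assert demiray_fung_stress_difference(d, MaterialModel(6e3, 2.0)).t_diff > base
        assert demiray_fung_stress_difference(d, MaterialModel(5e3, 3.0)).t_diff > base


class TestIncrementalModuli:
    @pytest.mark.parametrize("l1", [1.05, 1.2, 1.5])
    @pytest.mark.parametrize("b", [0.0, 1.0, 5.0])
    @pytest.mark.parametrize("mu0", [1e3, 10e3, 50e3])
    def test_closed_forms_match_finite_differences(self, l1, b, mu0):
        d = stretches_from_volumes(l1**3, 1.0)
        got = incremental_moduli(d, MaterialModel(mu0, b))
        alpha, gamma, beta2 = fd_moduli(l1, spherical_l2(l1), mu0, b)
        assert got.alpha == pytest.approx(alpha, rel=1e-6)
        assert got.gamma == pytest.approx(gamma, rel=1e-6)
        assert got.beta2 == pytest.approx(beta2, rel=1e-6)

    def test_classical_limit(self):
        mu0 = 20e3
        l1 = 1.0 + 1e-6
        d = stretches_from_volumes(l1**3, 1.0)
        got = incremental_moduli(d, MaterialModel(mu0, 5.0))
        assert got.alpha == pytest.approx(mu0, rel=1e-3)
        assert got.gamma == pytest.approx(mu0, rel=1e-3)
        assert got.beta2 == pytest.approx(2 * mu0, rel=1e-3)

    @given(st.floats(1.01, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_alpha_gamma_ratio(self, l1):
        d = stretches_from_volumes(l1**3, 1.0)
        got = incremental_moduli(d, MaterialModel(8e3, 3.0))
        assert got.alpha / got.gamma == pytest.approx(d.lam1**2 / d.lam2**2,
                                                      rel=1e-12)

    def test_beta_variants_disagree_off_identity(self):
        d = stretches_from_volumes(1.5, 1.0)
        m = MaterialModel(10e3, 5.0)
        b_derived = incremental_moduli(d, m, "derived").beta2
        b_17 = incremental_moduli(d, m, "eq17").beta2
        b_19 = incremental_moduli(d, m, "eq19").beta2
        assert len({round(b_derived), round(b_17), round(b_19)}) == 3

    def test_unknown_variant_rejected(self):
        d = stretches_from_volumes(1.5, 1.0)
        with pytest.raises(ValueError):
            incremental_moduli(d, MaterialModel(1e3, 1.0), "bogus")


class TestModuliFromPressure:
    def test_zero_pressure_zero_moduli(self, default_geometry):
        m = moduli_from_pressure(0.0, default_geometry, 5.0)
        assert m.alpha == m.gamma == m.beta2 == 0.0

    def test_negative_pressure_rejected(self, default_geometry):
        with pytest.raises(ValueError):
            moduli_from_pressure(-1.0, default_geometry, 5.0)

    def test_equivalent_to_material_path(self):
        """The pressure path (which never sees mu0) must reproduce the
        material path when P comes from the same forward mechanics."""
        mat = MaterialModel(mu0=20e3, b_stiff=5.0)
        V0 = 2e-4
        geom = CompartmentGeometry(V=1.5 * V0, V0=V0, h0=2.75e-3)
        P = pressure_from_volume(geom, mat)
        via_p = moduli_from_pressure(P, geom, mat.b_stiff)
        direct = incremental_moduli(geom.stretches, mat)
        assert via_p.alpha == pytest.approx(direct.alpha, rel=1e-9)
        assert via_p.gamma == pytest.approx(direct.gamma, rel=1e-9)
        assert via_p.beta2 == pytest.approx(direct.beta2, rel=1e-9)

    def test_b_coefficient_limit_near_reference_volume(self):
        """B*t_diff stays consistent with the direct beta2 as V -> V0."""
        mat = MaterialModel(mu0=20e3, b_stiff=5.0)
        V0 = 2e-4
        for eps in (1e-3, 1e-5):
            geom = CompartmentGeometry(V=(1 + eps) * V0, V0=V0, h0=2.75e-3)
            P = pressure_from_volume(geom, mat)
            via_p = moduli_from_pressure(P, geom, mat.b_stiff)
            direct = incremental_moduli(geom.stretches, mat)
            assert via_p.beta2 == pytest.approx(direct.beta2, rel=1e-6)

    def test_coefficients_singular_at_reference_volume(self):
        with pytest.raises(ValueError):
            stretch_coefficients(1.0, 1.0, 5.0)


class TestForwardPressure:
    def test_monotone_in_volume(self, soft_material):
        V0 = 2e-4
        vols = np.linspace(1.05, 4.0, 60) * V0
        P = [pressure_from_volume(CompartmentGeometry(V=v, V0=V0, h0=2.75e-3),
                                  soft_material) for v in vols]
        assert np.all(np.diff(P) > 0)

    def test_linear_in_mu0(self):
        V0 = 2e-4
        geom = CompartmentGeometry(V=1.4 * V0, V0=V0, h0=2.75e-3)
        p1 = pressure_from_volume(geom, MaterialModel(5e3, 5.0))
        p2 = pressure_from_volume(geom, MaterialModel(10e3, 5.0))
        assert p2 == pytest.approx(2.0 * p1, rel=1e-12)

    def test_thin_wall_consistency_bound(self, soft_material):
        """Log-law vs Laplace-law agreement within 2% while b/a <= 1.04."""
        V0 = 2e-4
        for ratio in (1.1, 1.3, 2.0):
            geom = CompartmentGeometry(V=ratio * V0, V0=V0, h0=2.75e-3)
            if geom.b_out / geom.a > 1.04:
                continue
            t = demiray_fung_stress_difference(geom.stretches,
                                               soft_material).t_diff
            P_thin = thin_wall_pressure(t, geom.h, geom.r)
            P_log = log_wall_pressure(t, geom.a, geom.b_out)
            assert abs(P_log - P_thin) / P_log <= 0.02
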