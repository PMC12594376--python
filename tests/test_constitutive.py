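"""Constitutive core: elasticity, damage, hardening, yield surface, viscosity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bonevpd import constitutive as con
from bonevpd.parameters import (
    DamageParameters,
    ElasticParameters,
    HardeningParameters,
    ParameterError,
    ViscosityParameters,
    YieldParameters,
)


def _isotropic(E=1000.0, nu=0.3):
    G = E / (2.0 * (1.0 + nu))
    return ElasticParameters(E, E, E, nu, nu, nu, G, G, G)


class TestElasticity:
    def test_isotropic_limit_matches_lame_closed_form(self):
        E, nu = 1000.0, 0.3
        S = con.build_stiffness(_isotropic(E, nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        expected = np.zeros((6, 6))
        expected[:3, :3] = lam
        expected[np.diag_indices(3)] = lam + 2 * mu
        expected[3:, 3:] = mu * np.eye(3)
        assert np.allclose(S, expected, rtol=1e-12, atol=1e-9)

    def test_cortical_stiffness_definite_and_axis1_stiffest(self, cortical):
        S = cortical.stiffness
        assert np.linalg.eigvalsh(S)[0] > 0
        assert S[0, 0] > S[1, 1]
        assert S[1, 1] == pytest.approx(S[2, 2], rel=1e-12)

    def test_stiffness_matches_compliance_inversion_oracle(self, cortical):
        # independent oracle: assemble the textbook orthotropic compliance
        # here and invert it with numpy
        ep = cortical.elastic
        C = np.zeros((6, 6))
        C[0, 0], C[1, 1], C[2, 2] = 1 / ep.E1, 1 / ep.E2, 1 / ep.E3
        C[0, 1] = C[1, 0] = -ep.nu12 / ep.E1
        C[1, 2] = C[2, 1] = -ep.nu23 / ep.E2
        C[0, 2] = C[2, 0] = -ep.nu31 / ep.E1
        C[3, 3], C[4, 4], C[5, 5] = 1 / ep.G12, 1 / ep.G23, 1 / ep.G31
        assert np.allclose(con.build_stiffness(ep), np.linalg.inv(C), rtol=1e-10)

    def test_compliance_is_stiffness_inverse(self, cortical, trabecular):
        for p in (cortical, trabecular):
            assert np.allclose(p.compliance @ p.stiffness, np.eye(6), atol=1e-10)

    def test_compliance_diagonal_is_inverse_modulus(self, cortical):
        assert cortical.compliance[0, 0] == pytest.approx(1.0 / 19900.0)

    def test_trabecular_compliance_symmetric(self, trabecular):
        C = trabecular.compliance
        assert np.abs(C - C.T).max() < 1e-12

    def test_inadmissible_constants_rejected(self):
        # nu12 large enough to destroy positive definiteness
        with pytest.raises(ParameterError, match="eigenvalue|positive"):
            ElasticParameters(1000, 1000, 1000, 0.9, 0.0, 0.9, 400, 400, 400)


class TestDamage:
    dp = DamageParameters(k0=1e-4, kp=5.0)

    def test_zero_below_and_at_threshold(self):
        assert con.damage_value(0.0, self.dp) == 0.0
        assert con.damage_value(self.dp.k0, self.dp) == 0.0

    def test_closed_form_half_damage(self):
        kappa = 1e-4 + math.log(2.0) / 5.0
        assert con.damage_value(kappa, self.dp) == pytest.approx(0.5, rel=1e-12)

    def test_bounded_continuous_non_decreasing(self):
        ks = np.linspace(0.0, 2.0, 2001)
        d = np.array([con.damage_value(k, self.dp) for k in ks])
        assert np.all((d >= 0.0) & (d < 1.0))
        assert np.all(np.diff(d) >= 0.0)
        assert np.max(np.abs(np.diff(d))) < 0.01  # no jumps on a fine grid

    def test_negative_kappa_rejected(self):
        with pytest.raises(ParameterError):
            con.damage_value(-1e-9, self.dp)


class TestHardening:
    hp = HardeningParameters(yr=5.0, sh=10.5, ks=0.01, ss=1.5)

    def test_starts_at_one_in_both_modes(self):
        assert con.hardening_value(0.0, self.hp, "original") == 1.0
        assert con.hardening_value(0.0, self.hp, "softening") == 1.0

    def test_original_mode_saturates_at_yr(self):
        assert con.hardening_value(1e3, self.hp, "original") == pytest.approx(5.0)
        ks = np.linspace(0, 1, 500)
        r = [con.hardening_value(k, self.hp, "original") for k in ks]
        assert np.all(np.diff(r) >= 0) and 1.0 <= min(r) and max(r) <= 5.0

    def test_softening_value_at_onset(self):
        # first branch evaluated at ks for the cortical constants
        expected = 1.0 + 4.0 * (1.0 - math.exp(-0.105))
        assert con.hardening_value(0.01, self.hp, "softening") == pytest.approx(expected)
        assert expected == pytest.approx(1.3987, abs=1e-4)

    def test_softening_continuous_at_onset_and_decays(self):
        eps = 1e-10
        below = con.hardening_value(self.hp.ks - eps, self.hp, "softening")
        above = con.hardening_value(self.hp.ks + eps, self.hp, "softening")
        assert above == pytest.approx(below, rel=1e-6)
        assert con.hardening_value(10.0, self.hp, "softening") < 1e-4  # -> 0
        ks = np.linspace(self.hp.ks, 1.0, 500)
        r = [con.hardening_value(k, self.hp, "softening") for k in ks]
        assert np.all(np.diff(r) <= 0)


class TestYieldSurface:
    def _symmetric_setup(self):
        ep = _isotropic()
        yp = YieldParameters(eps0p=0.002, eps0m=0.002, xi0=0.0)
        return yp, ep

    def test_symmetric_surface_is_centred_at_origin(self):
        yp, ep = self._symmetric_setup()
        yt = con.build_yield_tensors(yp, ep)
        assert np.allclose(yt.A, 0.0, atol=1e-12)

    @pytest.mark.parametrize("preset", ["cortical", "trabecular"])
    def test_surface_passes_through_six_calibration_states(self, preset, request):
        p = request.getfixturevalue(preset)
        yt = p.yield_tensors
        E = [p.elastic.E1, p.elastic.E2, p.elastic.E3]
        for i in range(3):
            for sign, eps0 in ((1, p.yield_.eps0p), (-1, p.yield_.eps0m)):
                sigma = np.zeros(6)
                sigma[i] = sign * E[i] * eps0
                assert abs(con.yield_value(sigma, 0.0, yt, p.hardening)) < 1e-8

    def test_cortical_tensile_yield_stress_from_strain(self, cortical):
        # surface crosses the axis-1 tension ray exactly at E1*eps0p
        sigma = np.zeros(6)
        sigma[0] = 19900.0 * 0.0018
        assert abs(con.yield_value(sigma, 0.0, cortical.yield_tensors, cortical.hardening)) < 1e-8

    def test_metric_tensor_symmetric_positive_definite(self, cortical, trabecular):
        for p in (cortical, trabecular):
            Af = p.yield_tensors.Afour
            assert np.allclose(Af, Af.T, atol=1e-15)
            assert np.linalg.eigvalsh(Af)[0] > 0

    def test_overly_strong_interaction_rejected(self):
        ep = _isotropic()
        with pytest.raises(ParameterError, match="convex"):
            con.build_yield_tensors(YieldParameters(0.002, 0.002, 1.5), ep)

    def test_value_at_origin_of_symmetric_surface(self):
        yp, ep = self._symmetric_setup()
        yt = con.build_yield_tensors(yp, ep)
        hp = HardeningParameters(yr=5.0, sh=10.5, ks=0.01, ss=1.5)
        assert con.yield_value(np.zeros(6), 0.0, yt, hp) == pytest.approx(-1.0)

    def test_degree_one_homogeneity_about_centre(self):
        yp, ep = self._symmetric_setup()
        yt = con.build_yield_tensors(yp, ep)
        hp = HardeningParameters(yr=5.0, sh=10.5, ks=0.01, ss=1.5)
        sigma = np.zeros(6)
        sigma[0] = ep.E1 * yp.eps0p  # on the surface: sqrt-form = 1
        assert con.yield_value(0.5 * sigma, 0.0, yt, hp) == pytest.approx(-0.5, abs=1e-10)

    def test_invariant_under_fabric_frame_rotation(self, cortical):
        # rotate fabric and stress together: the yield value must not change
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [30, -20, 45], degrees=True).as_matrix()
        yp = cortical.yield_
        yp_rot = YieldParameters(
            yp.eps0p, yp.eps0m, yp.xi0, tuple(R[0]), tuple(R[1]), tuple(R[2])
        )
        yt = cortical.yield_tensors
        yt_rot = con.build_yield_tensors(yp_rot, cortical.elastic)
        rng = np.random.default_rng(5)
        T_to_global = con.voigt_stress_rotation(R.T)
        for _ in range(10):
            sigma_mat = rng.normal(scale=50.0, size=6)  # material-frame stress
            y_mat = con.yield_value(sigma_mat, 0.0, yt, cortical.hardening)
            sigma_glob = T_to_global @ sigma_mat
            y_glob = con.yield_value(sigma_glob, 0.0, yt_rot, cortical.hardening)
            assert y_glob == pytest.approx(y_mat, rel=1e-9, abs=1e-12)


class TestYieldGradient:
    def test_matches_finite_differences_at_random_states(self, cortical):
        yt = cortical.yield_tensors
        hp = cortical.hardening
        rng = np.random.default_rng(0)
        for _ in range(100):
            sigma = rng.normal(scale=60.0, size=6)
            kappa = rng.uniform(0.0, 0.02)
            grad = con.yield_gradient(sigma, kappa, yt, hp)
            fd = np.empty(6)
            for i in range(6):
                h = 1e-4 * max(abs(sigma[i]), 1.0)
                sp, sm = sigma.copy(), sigma.copy()
                sp[i] += h
                sm[i] -= h
                fd[i] = (
                    con.yield_value(sp, kappa, yt, hp) - con.yield_value(sm, kappa, yt, hp)
                ) / (2 * h)
            assert np.allclose(grad, fd, rtol=1e-6, atol=1e-9)

    def test_radial_for_centred_isotropic_metric(self):
        # A = 0 and Afour proportional to identity: gradient parallel to stress
        yt = con.YieldTensors(A=np.zeros(6), Afour=np.eye(6) * 1e-4)
        hp = HardeningParameters(yr=5.0, sh=10.5, ks=0.01, ss=1.5)
        sigma = np.array([3.0, -1.0, 2.0, 0.5, 0.0, -0.25])
        grad = con.yield_gradient(sigma, 0.0, yt, hp)
        cosang = grad @ sigma / (np.linalg.norm(grad) * np.linalg.norm(sigma))
        assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_degree_zero_homogeneity(self, cortical):
        yt = cortical.yield_tensors
        hp = cortical.hardening
        r = con.hardening_value(0.005, hp)
        sigma = np.array([40.0, 5.0, -10.0, 3.0, 1.0, 0.0])
        g1 = con.yield_gradient(sigma, 0.005, yt, hp)
        sigma2 = 2.0 * (sigma - r * yt.A) + r * yt.A
        g2 = con.yield_gradient(sigma2, 0.005, yt, hp)
        assert np.allclose(g1, g2, rtol=1e-12)

    def test_undefined_at_surface_centre(self, cortical):
        yt = cortical.yield_tensors
        with pytest.raises(ParameterError):
            con.yield_gradient(yt.A * con.hardening_value(0.0, cortical.hardening),
                               0.0, yt, cortical.hardening)


class TestPerzyna:
    vp = ViscosityParameters(m=5.0, eta=0.01)

    def test_no_overstress_no_flow(self):
        assert con.perzyna_rate(0.0, self.vp) == 0.0
        assert con.overstress_phi(0.0, self.vp) == 0.0

    def test_direct_substitution(self):
        assert con.perzyna_rate(0.1, self.vp) == pytest.approx(51.0)
        assert con.overstress_phi(51.0, self.vp) == pytest.approx(0.1)

    def test_monotone_in_overstress(self):
        ys = np.linspace(0.0, 10.0, 200)
        gs = [con.perzyna_rate(y, self.vp) for y in ys]
        assert np.all(np.diff(gs) > 0)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ParameterError):
            con.perzyna_rate(-0.1, self.vp)
        with pytest.raises(ParameterError):
            con.overstress_phi(-1.0, self.vp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        m=st.floats(0.1, 50.0),
        eta=st.floats(1e-5, 100.0),
        Y=st.floats(0.0, 100.0),
    )
    def test_phi_and_rate_are_exact_inverses(self, m, eta, Y):
        vp = ViscosityParameters(m=m, eta=eta)
        back = con.overstress_phi(con.perzyna_rate(Y, vp), vp)
        assert back == pytest.approx(Y, rel=1e-10, abs=1e-12)


class TestGeneralizedYield:
    def test_elastic_state_equals_plain_yield(self, cortical):
        sigma = np.zeros(6)
        sigma[0] = 10.0  # well below the 35.8 MPa tensile yield
        ybar = con.generalized_yield(sigma, 0.0, 0.0, cortical)
        y = con.yield_value(sigma, 0.0, cortical.yield_tensors, cortical.hardening)
        assert ybar == pytest.approx(y) and ybar < 0

    def test_zero_rate_on_surface_gives_zero(self, cortical):
        sigma = np.zeros(6)
        sigma[0] = 19900.0 * 0.0018
        assert abs(con.generalized_yield(sigma, 0.0, 0.0, cortical)) < 1e-8
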