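"""Spectral densities, Redfield rates, and the spin-lock tilt correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssnmrdyn.constants import FieldContext, InteractionConstants
from ssnmrdyn.relaxation import (MotionModelEMF, MotionModelSMF,
                                 SpinLockGeometry, back_calculate,
                                 r1rho_to_r2, rate_R1, rate_R2, rate_eta,
                                 spectral_density_emf, spectral_density_smf)

OMEGAS = np.array([0.0, 1e7, 1e8, 5e8, 2e9])


class TestSpectralDensities:
    @pytest.mark.parametrize("omega", OMEGAS)
    def test_rigid_limit_annihilates_j(self, omega):
        assert spectral_density_smf(MotionModelSMF(1.0, 1e-9), omega) == 0.0

    def test_smf_zero_frequency_hand_value(self):
        j = spectral_density_smf(MotionModelSMF(0.82, 3.2e-11), 0.0)
        assert j == pytest.approx(5.76e-12, rel=1e-12)

    def test_smf_half_maximum_at_omega_tau_one(self):
        j = spectral_density_smf(MotionModelSMF(0.0, 1e-9), 1e9)
        assert j == pytest.approx(5e-10, rel=1e-12)

    def test_smf_even_in_omega(self):
        m = MotionModelSMF(0.5, 3e-9)
        assert np.allclose(spectral_density_smf(m, OMEGAS),
                           spectral_density_smf(m, -OMEGAS))

    def test_emf_collapses_to_smf_when_fast_rigid(self):
        emf = MotionModelEMF(1.0, 0.8, 1e-12, 5e-8)
        smf = MotionModelSMF(0.8, 5e-8)
        assert np.allclose(spectral_density_emf(emf, OMEGAS),
                           spectral_density_smf(smf, OMEGAS))

    def test_emf_collapses_to_smf_when_slow_rigid(self):
        emf = MotionModelEMF(0.9, 1.0, 1e-10, 1e-10)
        smf = MotionModelSMF(0.9, 1e-10)
        assert np.allclose(spectral_density_emf(emf, OMEGAS),
                           spectral_density_smf(smf, OMEGAS))

    def test_emf_zero_frequency_hand_value(self):
        j = spectral_density_emf(MotionModelEMF(0.9, 0.8, 1e-10, 5e-8), 0.0)
        assert j == pytest.approx(9.01e-9, rel=1e-12)

    def test_emf_fully_rigid(self):
        assert np.all(spectral_density_emf(
            MotionModelEMF(1.0, 1.0, 1e-10, 1e-8), OMEGAS) == 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(sf2=st.floats(0.0, 1.0), ss2=st.floats(0.0, 1.0),
           tau=st.floats(1e-12, 1e-6))
    def test_degenerate_time_scales_reduce_to_smf(self, sf2, ss2, tau):
        emf = MotionModelEMF(sf2, ss2, tau, tau)
        smf = MotionModelSMF(sf2 * ss2, tau)
        assert np.allclose(spectral_density_emf(emf, OMEGAS),
                           spectral_density_smf(smf, OMEGAS), rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MotionModelSMF(1.2, 1e-9)
        with pytest.raises(ValueError):
            MotionModelSMF(0.5, -1e-9)
        with pytest.raises(ValueError):
            MotionModelEMF(0.9, 0.8, 1e-8, 1e-10)   # tauf > taus


class TestRates:
    def test_rigid_model_relaxes_nothing(self, field14):
        m = MotionModelSMF(1.0, 1e-9)
        assert rate_R1(m, field14) == 0.0
        assert rate_R2(m, field14) == 0.0
        assert rate_eta(m, field14) == 0.0

    def test_r2_hand_evaluation(self, field14):
        # independent term-by-term evaluation with the pinned constants
        r2 = rate_R2(MotionModelSMF(0.82, 3.2e-8), field14)
        assert r2 == pytest.approx(8.188172733, rel=1e-9)

    def test_r1_eta_hand_evaluation(self, field14):
        m = MotionModelSMF(0.82, 3.2e-8)
        assert rate_R1(m, field14) == pytest.approx(0.08247747901, rel=1e-9)
        assert rate_eta(m, field14) == pytest.approx(7.227562849, rel=1e-9)

    def test_r2_linear_in_motional_amplitude(self, field14):
        tau = 5e-9
        r2_a = rate_R2(MotionModelSMF(0.9, tau), field14)
        r2_b = rate_R2(MotionModelSMF(0.8, tau), field14)
        assert r2_b == pytest.approx(2 * r2_a, rel=1e-12)

    def test_r1_unimodal_in_log_tau(self, field14):
        taus = np.logspace(-12, -6, 200)
        r1 = np.array([rate_R1(MotionModelSMF(0.9, t), field14) for t in taus])
        imax = int(np.argmax(r1))
        assert 0 < imax < len(taus) - 1
        diffs = np.sign(np.diff(r1))
        assert np.all(diffs[:imax] >= 0) and np.all(diffs[imax:] <= 0)
        # the maximum sits near |omega_N| tau = 1
        assert abs(math.log10(taus[imax] * abs(field14.omega_n))) < 0.3

    def test_r1_independent_of_omega_n_sign(self, field14):
        m = MotionModelSMF(0.85, 2e-9)
        flipped = FieldContext(field14.b0, field14.omega_h, -field14.omega_n)
        k = InteractionConstants.for_field(field14)
        assert rate_R1(m, flipped, k) == pytest.approx(
            rate_R1(m, field14, k), rel=1e-12)

    def test_r2_monotone_in_tau_at_fixed_amplitude(self, field14):
        taus = np.logspace(-12, -7, 100)
        r2 = np.array([rate_R2(MotionModelSMF(0.9, t), field14) for t in taus])
        assert np.all(np.diff(r2) > 0)

    def test_eta_vanishes_at_magic_angle(self, field14):
        m = MotionModelSMF(0.7, 5e-9)
        ref = rate_eta(m, field14, beta_deg=0.0)
        assert abs(rate_eta(m, field14, beta_deg=54.7356)) < 1e-5 * abs(ref)

    def test_eta_over_r2_j0_dominated_limit(self, field14):
        # with omega*tau >> 1 only the J(0) terms survive
        m = MotionModelSMF(0.5, 1e-5)
        k = InteractionConstants.for_field(field14)
        expected = (k.d * k.c / 15.0) / (k.d**2 / 20.0 + k.c**2 / 45.0)
        ratio = rate_eta(m, field14, k) / rate_R2(m, field14, k)
        assert ratio == pytest.approx(expected, rel=1e-3)

    def test_eta_bounded_by_r2_on_random_models(self, field14, rng):
        for _ in range(200):
            m = MotionModelSMF(rng.uniform(0, 1), 10 ** rng.uniform(-12, -6))
            assert abs(rate_eta(m, field14)) <= rate_R2(m, field14) + 1e-15

    @pytest.mark.parametrize("s2,tau", [(1.0 - 1e-9, 1e-9), (0.5, 1e-16)])
    def test_rates_vanish_in_rigid_and_fast_limits(self, field14, s2, tau):
        m = MotionModelSMF(s2, tau)
        assert rate_R1(m, field14) < 1e-6
        assert rate_R2(m, field14) < 1e-6
        assert abs(rate_eta(m, field14)) < 1e-6


class TestTiltCorrection:
    def test_on_resonance_identity(self):
        geom = SpinLockGeometry.from_theta(90.0)
        r2, flagged = r1rho_to_r2(5.0, 0.05, geom)
        assert r2 == 5.0 and not flagged

    def test_hand_evaluation_at_85_degrees(self):
        geom = SpinLockGeometry.from_theta(85.0)
        r2, _ = r1rho_to_r2(5.0, 0.05, geom)
        th = math.radians(85.0)
        assert r2 == pytest.approx(
            (5.0 - 0.05 * math.cos(th) ** 2) / math.sin(th) ** 2, rel=1e-12)
        assert r2 == pytest.approx(5.0379, abs=1e-4)

    def test_isotropic_case_returns_r1(self):
        for theta in (90.0, 75.0, 65.0):
            geom = SpinLockGeometry.from_theta(theta)
            r2, _ = r1rho_to_r2(0.7, 0.7, geom)
            assert r2 == pytest.approx(0.7, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r1=st.floats(0.01, 1.0), r2=st.floats(0.0, 50.0),
           theta=st.floats(61.0, 90.0))
    def test_forward_mixing_round_trip(self, r1, r2, theta):
        geom = SpinLockGeometry.from_theta(theta)
        th = math.radians(theta)
        r1rho = r2 * math.sin(th) ** 2 + r1 * math.cos(th) ** 2
        back, flagged = r1rho_to_r2(r1rho, r1, geom)
        assert back == pytest.approx(r2, abs=1e-9)
        assert not flagged

    def test_low_tilt_flagged(self):
        geom = SpinLockGeometry.from_theta(45.0)
        with pytest.warns(UserWarning):
            _, flagged = r1rho_to_r2(5.0, 0.05, geom)
        assert flagged

    def test_invalid_tilt_rejected(self):
        with pytest.raises(ValueError):
            SpinLockGeometry.from_theta(0.0)
        with pytest.raises(ValueError):
            r1rho_to_r2(-1.0, 0.05, SpinLockGeometry.from_theta(90.0))


class TestBackCalculate:
    def test_rigid_model_gives_zero_rates_unit_s2dip(self, field14):
        ds = back_calculate(MotionModelSMF(1.0, 1e-9),
                            [("R1", field14), ("R2", field14),
                             ("eta", field14), ("S2dip", None)])
        vals = {o.kind: o.value for o in ds.observations}
        assert vals["R1"] == vals["R2"] == vals["eta"] == 0.0
        assert vals["S2dip"] == 1.0

    def test_emf_total_order_parameter(self, field14):
        ds = back_calculate(MotionModelEMF(0.9, 0.8, 1e-10, 5e-8),
                            [("S2dip", None)])
        assert ds.observations[0].value == pytest.approx(0.72, rel=1e-12)

    def test_consistency_with_single_rate_operations(self, field14):
        m = MotionModelSMF(0.82, 3.2e-8)
        ds = back_calculate(m, [("R1", field14), ("R2", field14),
                                ("eta", field14)])
        vals = {o.kind: o.value for o in ds.observations}
        assert vals["R1"] == pytest.approx(rate_R1(m, field14), rel=1e-12)
        assert vals["R2"] == pytest.approx(rate_R2(m, field14), rel=1e-12)
        assert vals["eta"] == pytest.approx(rate_eta(m, field14), rel=1e-12)

    def test_unknown_kind_rejected(self, field14):
        with pytest.raises(ValueError):
            back_calculate(MotionModelSMF(0.8, 1e-9), [("R1rho", field14)])


def test_field_context_unit_conversions():
    f = FieldContext.from_proton_mhz(600.0)
    assert f.b0 == pytest.approx(14.09, abs=0.01)
    assert f.omega_h / f.omega_n == pytest.approx(2.67519e8 / -2.7116e7,
                                                  rel=1e-12)
    with pytest.raises(ValueError):
        FieldContext.from_tesla(-1.0)
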