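"""REDOR propagation, analytic oracles, coupling fits, and rf effects.

Simulation sizes (orientation counts, slice counts, time grids) are scaled to
keep the suite fast; convergence of these choices is asserted explicitly.
"""

import math

import numpy as np
import pytest
from scipy.special import jv

from ssnmrdyn.powder import beta_gamma_quadrature, zcw_orientations
from ssnmrdyn.redor import (CsaTensor, DephasingCurve, DipolarPair,
                            RedorExperiment, RedorLibrary, RfProfile,
                            SpinSite, SpinSystem, average_over_rf,
                            fit_dipolar_coupling, ideal_redor_curve,
                            pair_anisotropy_from_distance, simulate_redor,
                            two_spin_nh, three_spin_hhn)

MAS = 37037.0
EXP_IDEAL = RedorExperiment(mas_hz=MAS, n_rotor_periods=(0, 2, 4, 6, 8),
                            h_pulse=(0.0, 100e3), n_pulse=(0.0, 50e3))
EXP_FINITE = RedorExperiment(mas_hz=MAS, n_rotor_periods=(0, 2, 4, 6, 8),
                             h_pulse=(5e-6, 100e3), n_pulse=(10e-6, 50e3),
                             time_shift=3e-6)
GL = beta_gamma_quadrature(24, 16)


class TestAnisotropy:
    def test_inverse_cube_law(self):
        a1 = pair_anisotropy_from_distance(("1H", "15N"), 1.0)
        a2 = pair_anisotropy_from_distance(("1H", "15N"), 2.0)
        assert a1 / a2 == pytest.approx(8.0, rel=1e-12)

    def test_nh_bond_value_exceeds_effective_default(self):
        # 1.02 A gives ~22.95 kHz; the simulation default is the effective
        # 20.4 kHz -- both are exposed deliberately
        a = pair_anisotropy_from_distance(("1H", "15N"), 1.02)
        assert a == pytest.approx(22946.0, abs=1.0)
        assert two_spin_nh().nh_pair().aniso_hz == 20400.0

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            pair_anisotropy_from_distance(("1H", "1H"), -1.0)


class TestIdealCurve:
    def test_zero_coupling_no_dephasing(self):
        c = ideal_redor_curve(0.0, EXP_IDEAL.times(), MAS)
        assert np.allclose(c.values, 0.0, atol=1e-12)

    def test_matches_bessel_closed_form(self):
        # standard (unshifted) REDOR universal curve
        times = np.arange(0, 13, 2) / MAS
        c = ideal_redor_curve(20400.0, times, MAS)
        lam = times * 10200.0
        with np.errstate(invalid="ignore"):
            bess = 1 - (math.sqrt(2) * math.pi / 4) * jv(0.25, math.sqrt(2) * lam) \
                * jv(-0.25, math.sqrt(2) * lam)
        bess[0] = 0.0
        assert np.allclose(c.values, bess, atol=2e-3)

    def test_long_time_plateau(self):
        # the universal curve settles on a plateau of 1; its oscillation
        # envelope decays roughly as 1/(pi sqrt(2) lambda), so +-0.02 holds
        # once lambda = D t is large enough
        times = np.concatenate([[0], np.arange(88, 111, 2)]) / MAS
        c = ideal_redor_curve(20400.0, times, MAS, n_beta=256, n_gamma=128)
        assert np.all(np.abs(c.values[1:] - 1.0) < 0.02)

    def test_time_shift_slows_dephasing(self):
        tr = 1.0 / MAS
        first_points = []
        for ts in (0.0, tr / 8, tr / 5):
            c = ideal_redor_curve(20400.0, EXP_IDEAL.times(), MAS,
                                  time_shift=ts)
            first_points.append(c.values[1])
        # larger shifts scale the recoupled interaction further down
        assert first_points[0] > first_points[1] > first_points[2] > 0

    def test_nonsynchronous_times_rejected(self):
        with pytest.raises(ValueError):
            ideal_redor_curve(20400.0, np.array([0.0, 1.3e-5]), MAS)


class TestSimulator:
    def test_no_coupling_means_no_dephasing(self):
        sites = [SpinSite("15N", offset_hz=100.0), SpinSite("1H", offset_hz=600.0)]
        system = SpinSystem(sites, [DipolarPair(0, 1, 0.0)])
        c = simulate_redor(system, EXP_FINITE, orientations=GL,
                           slices_per_rotor=32)
        assert np.allclose(c.values, 0.0, atol=1e-9)

    def test_delta_pulse_limit_matches_analytic_oracle(self):
        sim = simulate_redor(two_spin_nh(20400.0), EXP_IDEAL, orientations=GL)
        ideal = ideal_redor_curve(20400.0, EXP_IDEAL.times(), MAS)
        rms = np.sqrt(np.mean((sim.values - ideal.values) ** 2))
        assert rms < 0.01

    def test_delta_pulse_limit_with_time_shift(self):
        exp = RedorExperiment(mas_hz=MAS, n_rotor_periods=(0, 2, 4, 6, 8),
                              h_pulse=(0.0, 100e3), n_pulse=(0.0, 50e3),
                              time_shift=3e-6)
        sim = simulate_redor(two_spin_nh(20400.0), exp, orientations=GL)
        ideal = ideal_redor_curve(20400.0, exp.times(), MAS, time_shift=3e-6)
        assert np.sqrt(np.mean((sim.values - ideal.values) ** 2)) < 0.01

    def test_slice_halving_convergence(self):
        sys2 = two_spin_nh(20400.0)
        a = simulate_redor(sys2, EXP_FINITE, orientations=GL, slices_per_rotor=50)
        b = simulate_redor(sys2, EXP_FINITE, orientations=GL, slices_per_rotor=100)
        assert np.sqrt(np.mean((a.values - b.values) ** 2)) < 0.002

    def test_powder_doubling_convergence(self):
        sys2 = two_spin_nh(20400.0)
        a = simulate_redor(sys2, EXP_FINITE, zcw_orientations(144, 16),
                           slices_per_rotor=32)
        b = simulate_redor(sys2, EXP_FINITE, zcw_orientations(288, 16),
                           slices_per_rotor=32)
        assert np.sqrt(np.mean((a.values - b.values) ** 2)) < 0.002

    def test_curves_bounded(self):
        times = np.arange(0, 17, 2)
        exp = RedorExperiment(mas_hz=MAS, n_rotor_periods=tuple(times),
                              h_pulse=(5e-6, 100e3), n_pulse=(10e-6, 50e3),
                              time_shift=3e-6)
        c = simulate_redor(two_spin_nh(20400.0), exp, orientations=GL,
                           slices_per_rotor=32)
        assert np.all(c.values >= -0.05) and np.all(c.values <= 1.15)
        assert c.values[0] == 0.0

    def test_phase_schemes_differ_with_misset_pulses(self):
        sys3 = three_spin_hhn()
        ori = zcw_orientations(30, 8)
        kw = dict(mas_hz=MAS, n_rotor_periods=(0, 4, 8),
                  h_pulse=(5e-6, 90e3), n_pulse=(10e-6, 50e3), time_shift=3e-6)
        cont = simulate_redor(sys3, RedorExperiment(phase_scheme="xy8_continuous",
                                                    **kw),
                              orientations=ori, slices_per_rotor=32)
        mirr = simulate_redor(sys3, RedorExperiment(phase_scheme="xy8_mirror",
                                                    **kw),
                              orientations=ori, slices_per_rotor=32)
        assert np.max(np.abs(cont.values - mirr.values)) > 1e-4

    def test_csa_perturbs_fitted_coupling_below_half_percent(self):
        lib = RedorLibrary(EXP_FINITE.times(), MAS, EXP_FINITE.time_shift)
        bare = two_spin_nh(20400.0)
        with_csa = SpinSystem(
            [SpinSite("15N", offset_hz=100.0,
                      csa=CsaTensor(2500.0, 0.3, (0.0, 20.0, 0.0))),
             SpinSite("1H", offset_hz=600.0,
                      csa=CsaTensor(1200.0, 0.0, (0.0, 29.0, 0.0)))],
            [DipolarPair(0, 1, 20400.0)])
        ori = zcw_orientations(50, 8)
        f_bare = lib.fit(simulate_redor(bare, EXP_FINITE, ori,
                                        slices_per_rotor=32), n_mc=0)
        f_csa = lib.fit(simulate_redor(with_csa, EXP_FINITE, ori,
                                       slices_per_rotor=32), n_mc=0)
        assert abs(f_csa.delta_hz - f_bare.delta_hz) / f_bare.delta_hz < 0.005


class TestExperimentValidation:
    def test_pulse_overlap_rejected(self):
        exp = RedorExperiment(mas_hz=MAS, n_rotor_periods=(4,),
                              h_pulse=(5e-6, 100e3), n_pulse=(10e-6, 50e3),
                              time_shift=5e-6)
        with pytest.raises(ValueError, match="overlap"):
            simulate_redor(two_spin_nh(), exp, orientations=zcw_orientations(4, 2),
                           slices_per_rotor=16)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RedorExperiment(mas_hz=MAS, n_rotor_periods=(0, 3))
        with pytest.raises(ValueError):
            RedorExperiment(mas_hz=MAS, time_shift=1.0)
        with pytest.raises(ValueError):
            RedorExperiment(mas_hz=MAS, h_pulse=(2e-5, 100e3))
        with pytest.raises(ValueError):
            SpinSystem([SpinSite("1H"), SpinSite("1H")], [])

    def test_dephasing_curve_validation(self):
        with pytest.raises(ValueError):
            DephasingCurve(np.array([0.0, 1e-4]), np.array([0.5, 0.6]))


class TestCouplingFit:
    def test_round_trip_identity(self):
        c = ideal_redor_curve(20400.0, EXP_IDEAL.times(), MAS)
        lib = RedorLibrary(EXP_IDEAL.times(), MAS)
        fit = fit_dipolar_coupling(c, lib, n_mc=0)
        assert abs(fit.delta_hz - 20400.0) <= lib.grid_step

    def test_all_zero_curve_fits_zero(self):
        c = DephasingCurve(EXP_IDEAL.times(), np.zeros(5),
                           np.full(5, 0.02))
        lib = RedorLibrary(EXP_IDEAL.times(), MAS)
        fit = fit_dipolar_coupling(c, lib, n_mc=0)
        assert fit.delta_hz <= lib.grid_step
        assert "grid_edge" in fit.flags

    def test_mc_error_positive_and_reproducible(self):
        c = ideal_redor_curve(15000.0, EXP_IDEAL.times(), MAS)
        noisy = DephasingCurve(c.times, c.values, np.full(len(c.times), 0.02))
        lib = RedorLibrary(EXP_IDEAL.times(), MAS)
        a = fit_dipolar_coupling(noisy, lib, n_mc=300, seed=4)
        b = fit_dipolar_coupling(noisy, lib, n_mc=300, seed=4)
        assert a.sigma_hz == b.sigma_hz > 0


class TestRfProfile:
    def test_threshold_and_normalisation(self):
        p = RfProfile(np.array([95e3, 100e3, 105e3]),
                      np.array([0.05, 1.0, 0.2]), threshold=0.1)
        assert p.weights[0] == 0.0
        assert p.weights.sum() == pytest.approx(1.0)

    def test_delta_profile_equals_single_simulation(self):
        sys2 = two_spin_nh(20400.0)
        ori = zcw_orientations(30, 8)
        avg = average_over_rf(sys2, EXP_FINITE, RfProfile.delta(100e3),
                              orientations=ori, slices_per_rotor=32)
        single = simulate_redor(sys2, EXP_FINITE, orientations=ori,
                                slices_per_rotor=32)
        assert np.allclose(avg.values, single.values, atol=1e-12)

    def test_symmetric_spread_reduces_apparent_coupling(self):
        sys2 = two_spin_nh(20400.0)
        ori = zcw_orientations(30, 8)
        lib = RedorLibrary(EXP_FINITE.times(), MAS, EXP_FINITE.time_shift)
        sym = RfProfile(np.array([95e3, 105e3]), np.array([0.5, 0.5]))
        f_sym = lib.fit(average_over_rf(sys2, EXP_FINITE, sym, ori,
                                        slices_per_rotor=32), n_mc=0)
        f_nom = lib.fit(simulate_redor(sys2, EXP_FINITE, ori,
                                       slices_per_rotor=32), n_mc=0)
        assert f_sym.delta_hz <= f_nom.delta_hz + 1e-9

    def test_low_tailed_profile_strictly_reduces_coupling(self):
        sys2 = two_spin_nh(20400.0)
        ori = zcw_orientations(30, 8)
        lib = RedorLibrary(EXP_FINITE.times(), MAS, EXP_FINITE.time_shift)
        low = RfProfile(np.array([90e3, 95e3, 100e3]),
                        np.array([0.2, 0.3, 0.5]))
        f_low = lib.fit(average_over_rf(sys2, EXP_FINITE, low, ori,
                                        slices_per_rotor=32), n_mc=0)
        f_nom = lib.fit(simulate_redor(sys2, EXP_FINITE, ori,
                                       slices_per_rotor=32), n_mc=0)
        assert f_low.delta_hz < f_nom.delta_hz

    def test_packaged_profile_loads_and_matches_generator(self):
        from importlib import resources
        path = resources.files("ssnmrdyn.data") / "rf_profile_synthetic.txt"
        p = RfProfile.from_file(str(path))
        gen = RfProfile.synthetic_solenoid()
        assert np.allclose(p.grid_hz, gen.grid_hz)
        assert np.allclose(p.weights, gen.weights, atol=1e-5)

    def test_synthetic_profile_shape(self):
        p = RfProfile.synthetic_solenoid()
        grid, w = p.grid_hz, p.weights
        peak = grid[np.argmax(w)]
        low_mass = w[grid < peak].sum()
        high_mass = w[grid > peak].sum()
        assert low_mass > high_mass      # broader tail towards low rf
        with pytest.raises(ValueError):
            RfProfile(np.array([]), np.array([]))
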