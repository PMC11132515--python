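"""Classic Kuramoto simulation, regression fitting, bifurcation and timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairsync._circular import TWO_PI, wrap
from pairsync.kuramoto import (DegenerateRegressorError, KuramotoParams,
                               critical_coupling, equilibrium_curve,
                               fit_classic, frame_rate_to_dt,
                               head_speed_to_cycles, mae, predict_phi,
                               saddle_node_point, simulate_classic,
                               time_to_antiphase)
from pairsync.phase import PhaseDifferenceSeries


def _phi_series(phi, rate=25.0):
    return PhaseDifferenceSeries(rate_hz=rate, phi=phi, phi_wrapped=wrap(phi))


class TestSimulateClassic:
    def test_uncoupled_linear_phases(self):
        p = KuramotoParams(omega1_cycles=0.2, omega2_cycles=0.3, K=0.0,
                           duration_s=10.0)
        _, _, phi = simulate_classic(p)
        assert phi.phi[-1] - phi.phi[0] == pytest.approx(TWO_PI * 0.1 * 10.0)

    def test_antiphase_approach_is_monotone(self):
        p = KuramotoParams(omega1_cycles=0.2, omega2_cycles=0.2, K=-1.0,
                           duration_s=30.0, theta0=(0.0, np.pi / 2))
        _, _, phi = simulate_classic(p)
        d = np.diff(phi.phi)
        assert np.all(d >= -1e-12)
        assert phi.phi[-1] == pytest.approx(np.pi, abs=0.02)

    def test_unstable_equilibrium_preserved_exactly(self):
        p = KuramotoParams(omega1_cycles=0.2, omega2_cycles=0.2, K=-1.0,
                           duration_s=10.0, theta0=(0.3, 0.3))
        _, _, phi = simulate_classic(p)
        assert np.all(phi.phi == 0.0)

    def test_coarse_step_warns(self):
        p = KuramotoParams(omega1_cycles=0.1, omega2_cycles=0.1, K=-20.0,
                           duration_s=1.0)
        with pytest.warns(RuntimeWarning, match="Euler"):
            simulate_classic(p)


class TestFitClassic:
    def test_exact_recovery_on_noiseless_euler_output(self):
        Omega, K = 0.3, -1.2
        p = KuramotoParams(omega1_cycles=0.0, omega2_cycles=Omega / TWO_PI,
                           K=K, duration_s=60.0, theta0=(0.0, 0.5))
        _, _, phi = simulate_classic(p)
        fit = fit_classic(phi, edge_trim_s=0.0)
        assert fit.K == pytest.approx(K, rel=1e-10)
        assert fit.Omega == pytest.approx(Omega, rel=1e-10)
        assert fit.Kc == pytest.approx(-abs(Omega))
        assert fit.mae_rad < 1e-9

    def test_constant_phi_rejected(self):
        with pytest.raises(DegenerateRegressorError):
            fit_classic(_phi_series(np.full(500, 0.7)), edge_trim_s=0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="few frames"):
            fit_classic(_phi_series(np.linspace(0, 1, 8)), edge_trim_s=0.0)

    def test_noisy_recovery_on_drifting_trajectory(self, rng):
        """Additive white phase noise leaves the fit centered on the truth
        when Phi keeps drifting (|K| < |Omega|), where the differenced
        noise decorrelates from the sin regressor over full cycles."""
        Omega, K = 2.0, -0.8
        estimates = []
        for _ in range(100):
            p = KuramotoParams(omega1_cycles=0.0, omega2_cycles=Omega / TWO_PI,
                               K=K, duration_s=60.0, theta0=(0.0, 0.5))
            _, _, phi = simulate_classic(p)
            noisy = phi.phi + rng.normal(0, 0.05, len(phi))
            fit = fit_classic(_phi_series(noisy), edge_trim_s=0.0)
            estimates.append(fit.K)
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - K) < 3 * estimates.std()

    def test_noise_on_locked_trajectory_biases_fit(self, rng):
        """On a phase-locked trajectory, differenced measurement noise
        correlates with the regressor and drags K negative -- a known
        property of the Euler-regression estimator worth pinning down."""
        Omega, K = 0.3, -1.2
        estimates = []
        for _ in range(20):
            p = KuramotoParams(omega1_cycles=0.0, omega2_cycles=Omega / TWO_PI,
                               K=K, duration_s=60.0, theta0=(0.0, 0.5))
            _, _, phi = simulate_classic(p)
            noisy = phi.phi + rng.normal(0, 0.05, len(phi))
            fit = fit_classic(_phi_series(noisy), edge_trim_s=0.0)
            estimates.append(fit.K)
        assert np.mean(estimates) < K  # more negative than the truth

    @settings(max_examples=15, deadline=None)
    @given(st.floats(-2.0, 2.0), st.floats(-4.0, 4.0),
           st.floats(-2.5, 2.5))
    def test_roundtrip_property(self, Omega, K, phi0):
        """simulate -> fit inverts exactly whenever the regressor varies."""
        p = KuramotoParams(omega1_cycles=0.0, omega2_cycles=Omega / TWO_PI,
                           K=K, duration_s=40.0, theta0=(0.0, phi0))
        _, _, phi = simulate_classic(p)
        if np.ptp(np.sin(phi.phi_wrapped[:-1])) < 1e-6:
            return
        fit = fit_classic(phi, edge_trim_s=0.0)
        assert fit.K == pytest.approx(K, abs=1e-8)
        assert fit.Omega == pytest.approx(Omega, abs=1e-8)


class TestCriticalCoupling:
    @pytest.mark.parametrize("Omega,expected", [(0.38, -0.38), (-0.38, -0.38),
                                                (0.0, 0.0)])
    def test_values(self, Omega, expected):
        assert critical_coupling(Omega) == expected

    def test_even_and_nonpositive(self, rng):
        for w in rng.normal(0, 2, 20):
            assert critical_coupling(w) == critical_coupling(-w) <= 0


class TestEquilibriumCurve:
    def test_saddle_node_single_equilibrium_at_plus_one(self):
        curve = equilibrium_curve(np.array([1.0]))
        phis = np.sort(curve["phi"].unique())
        assert np.allclose(phis, np.pi / 2)

    def test_saddle_node_at_minus_one(self):
        curve = equilibrium_curve(np.array([-1.0]))
        assert np.allclose(np.sort(curve["phi"].unique()), -np.pi / 2)

    def test_strong_negative_ratio_stable_near_minus_pi(self):
        curve = equilibrium_curve(np.array([-10.0]))
        stable = curve[curve["stable"]]
        assert stable["phi"].iloc[0] == pytest.approx(-np.pi + np.arcsin(0.1),
                                                      abs=1e-9)

    def test_no_real_equilibria_inside_unit_interval(self):
        assert equilibrium_curve(np.linspace(-0.99, 0.99, 21)).empty

    def test_saddle_node_location_by_bisection(self):
        assert saddle_node_point(-1) == pytest.approx(-1.0, abs=1e-9)
        assert saddle_node_point(+1) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("ratio", [-3.0, -1.5, 2.0])
    def test_stability_by_perturbation(self, ratio):
        """Simulating from Phi* +/- 0.01 returns to stable, leaves unstable."""
        Omega = 0.4
        K = ratio * Omega
        curve = equilibrium_curve(np.array([ratio]))
        stable = float(curve[curve["stable"]]["phi"].iloc[0])
        unstable = float(curve[~curve["stable"]]["phi"].iloc[0])
        for eq, should_return in ((stable, True), (unstable, False)):
            phi = predict_phi(eq + 0.01, Omega, K, 2000, 0.01)
            d_end = abs(wrap(phi[-1] - eq))
            if should_return:
                assert d_end < 0.01
            else:
                assert d_end > 0.05


class TestTimeToAntiphase:
    def test_closed_form_matches_integration(self):
        T, src = time_to_antiphase(np.pi / 2, 0.0, -1.0)
        assert src == "closed_form"
        # direct quadrature of dPhi/(Omega - K sin Phi) to the stop point
        from scipy.integrate import quad
        target = np.pi - 0.01
        T_quad, _ = quad(lambda u: 1.0 / np.sin(u), np.pi / 2, target)
        assert T == pytest.approx(T_quad, rel=0.01)

    def test_marginal_coupling_not_reached(self):
        T, src = time_to_antiphase(0.5, 0.3, -0.3)
        assert T is None and src == "not reached"

    def test_already_at_stable_equilibrium(self):
        Omega, K = 0.3, -1.0
        stable = wrap(-np.pi - np.arcsin(Omega / K))
        T, _ = time_to_antiphase(stable, Omega, K)
        assert T == 0.0

    def test_unstable_start_flagged_infinite(self):
        Omega, K = 0.3, -1.0
        T, src = time_to_antiphase(np.arcsin(Omega / K), Omega, K)
        assert np.isinf(T) and "unstable" in src

    def test_monotone_in_coupling_strength(self):
        Ts = [time_to_antiphase(0.5, 0.3, K)[0]
              for K in (-0.8, -1.2, -2.0, -3.5)]
        assert all(a > b for a, b in zip(Ts, Ts[1:]))


class TestMae:
    def test_identical_zero(self):
        x = np.linspace(0, 5, 100)
        assert mae(x, x) == 0.0

    def test_constant_offsets_wrap(self):
        x = np.zeros(50)
        assert mae(x, x + np.pi / 2) == pytest.approx(np.pi / 2)
        assert mae(x, x + 3 * np.pi / 2) == pytest.approx(np.pi / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros(5), np.zeros(6))


def test_unit_conversions():
    assert head_speed_to_cycles(1000.0) == pytest.approx(2.78, abs=0.005)
    assert frame_rate_to_dt(25.0) == pytest.approx(0.04)
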