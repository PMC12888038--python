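"""Core dynamics: load components, signals, integration, entrapment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import nerdsim as ns
from nerdsim import (
    ConfigError, ContractError, DomainError, InjurySignal, ModelConfig,
    NerdParameters, ReceptorExtension,
)
from conftest import random_parameters

ALL_HALF = NerdParameters(*[0.5] * 12)
ALL_ONE = NerdParameters(*[1.0] * 12)
SHORTFALL = ModelConfig()
LITERAL = ModelConfig(collapse_convention="literal")


class TestInjurySignal:
    @pytest.mark.parametrize("t", [0.0, 1.5, 100.0])
    def test_constant_is_time_invariant(self, t):
        sig = InjurySignal("constant", magnitude=0.6)
        assert ns.evaluate_injury(sig, t) == 0.6

    def test_exp_decay_closed_form(self):
        sig = InjurySignal("exp_decay", magnitude=1.0, tau=4.0)
        assert ns.evaluate_injury(sig, 4.0) == pytest.approx(np.exp(-1.0), abs=1e-10)

    def test_piecewise_levels(self):
        sig = InjurySignal("piecewise_constant", breakpoints=(1.0, 3.0), levels=(2.0, 1.0, 0.0))
        assert sig.evaluate(0.5) == 2.0
        assert sig.evaluate(1.0) == 1.0  # right-continuous at breakpoints
        assert sig.evaluate(10.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            InjurySignal("constant", magnitude=1.0).evaluate(-1.0)

    def test_invalid_configs(self):
        with pytest.raises(ConfigError):
            InjurySignal("sawtooth", magnitude=1.0)
        with pytest.raises(ConfigError):
            InjurySignal("exp_decay", magnitude=1.0, tau=-2.0)
        with pytest.raises(ConfigError):
            InjurySignal("piecewise_constant", breakpoints=(3.0, 1.0), levels=(1, 1, 1))
        with pytest.raises(DomainError):
            InjurySignal("constant", magnitude=-0.1)

    @pytest.mark.parametrize("sig", [
        InjurySignal("constant", magnitude=0.7),
        InjurySignal("exp_decay", magnitude=2.0, tau=3.0),
        InjurySignal("piecewise_constant", breakpoints=(1.2, 4.7), levels=(2.0, 0.5, 0.1)),
    ])
    def test_integral_matches_quadrature(self, sig):
        for t in (0.0, 0.9, 2.5, 8.0):
            expected = quad(sig.evaluate, 0, t, points=[1.2, 4.7], limit=200)[0]
            assert sig.integral(t) == pytest.approx(expected, abs=1e-9)


class TestParameterValidation:
    def test_coefficients_must_be_unit_interval(self):
        with pytest.raises(DomainError):
            NerdParameters(*([0.5] * 11 + [1.2]))
        with pytest.raises(DomainError):
            ALL_HALF.updated(G0=-0.1)
        with pytest.raises(DomainError):
            ALL_HALF.updated(N0=0.0)

    def test_dict_round_trip(self):
        d = ALL_HALF.as_dict()
        assert NerdParameters.from_dict(d) == ALL_HALF


class TestLoadComponents:
    def test_zero_injury_gives_zero_behavioral_load(self):
        assert ns.behavioral_load(ALL_HALF, 0.0, 0.0) == 0.0

    def test_all_ones_unit_reflex_injury(self):
        # chi*(kappa*gamma*alpha + nu*rho*lambda*mu*gamma*alpha) = 1 + 1
        assert ns.behavioral_load(ALL_ONE, 1.0, 0.0) == pytest.approx(2.0)

    def test_half_coefficients_substitution(self):
        assert ns.behavioral_load(ALL_HALF, 1.0, 1.0) == pytest.approx(0.1328125, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            ns.behavioral_load(ALL_HALF, -1.0, 0.0)

    def test_shortfall_zero_at_zero_injury(self):
        assert ns.gain_collapse(ALL_HALF, 0.0, 0.0, SHORTFALL) == 0.0

    def test_literal_equals_psi_g0_at_zero_injury(self):
        p = ALL_HALF.updated(G0=1.0)
        assert ns.gain_collapse(p, 0.0, 0.0, LITERAL) == pytest.approx(0.5)

    def test_literal_substitution(self):
        assert ns.gain_collapse(ALL_HALF, 1.0, 1.0, LITERAL) == pytest.approx(0.09375, abs=1e-12)

    def test_receptor_extension_requires_support_value(self):
        with pytest.raises(ContractError):
            ns.gain_collapse(ALL_HALF, 1.0, 1.0, LITERAL, H_t=None, receptor_enabled=True)

    def test_dn_dt_zero_injury_shortfall(self):
        assert ns.dN_dt(ALL_HALF, 0.0, 0.0, SHORTFALL) == 0.0

    def test_dn_dt_literal_zero_injury(self):
        p = ALL_HALF.updated(eta=0.2, psi=0.5, G0=1.0)
        assert ns.dN_dt(p, 0.0, 0.0, LITERAL) == pytest.approx(-0.1)

    def test_dn_dt_substitution(self):
        assert ns.dN_dt(ALL_HALF, 1.0, 1.0, SHORTFALL) == pytest.approx(-0.26953125, abs=1e-12)

    def test_linearity_in_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_parameters(rng)
            i1, c1, i2, c2 = rng.uniform(0, 3, size=4)
            assert ns.behavioral_load(p, i1 + i2, c1 + c2) == pytest.approx(
                ns.behavioral_load(p, i1, c1) + ns.behavioral_load(p, i2, c2), rel=1e-12)


class TestReceptorSupport:
    def test_decoupled_returns_reserve(self):
        ext = ReceptorExtension(enabled=True, zeta=0.0, R0=5.0, R_stim=3.0)
        assert ns.receptor_gain_support(ext, 0.0, 1.0) == 1.0

    def test_clamped_at_zero(self):
        ext = ReceptorExtension(enabled=True, zeta=0.5, R0=-4.0)
        assert ns.receptor_gain_support(ext, 1.0, 1.0) == 0.0

    def test_direct_substitution(self):
        ext = ReceptorExtension(enabled=True, zeta=0.5, R0=0.2, R_stim=0.3, R_loss=-0.1)
        assert ns.receptor_gain_support(ext, 0.0, 1.0) == pytest.approx(1.2)

    def test_disabled_extension_rejected(self):
        with pytest.raises(ContractError):
            ns.receptor_gain_support(ReceptorExtension(enabled=False), 0.0, 1.0)

    def test_signal_time_courses(self):
        ext = ReceptorExtension(
            enabled=True, zeta=1.0, R0=0.0,
            R_stim=InjurySignal("exp_decay", magnitude=1.0, tau=2.0),
            R_loss=InjurySignal("constant", magnitude=0.2),
        )
        expected = max(0.0, 1.0 + (np.exp(-1.0) - 0.2))
        assert ns.receptor_gain_support(ext, 2.0, 1.0) == pytest.approx(expected)

    @given(zeta=st.floats(0, 1), r0=st.floats(-5, 5), rs=st.floats(0, 5),
           rl=st.floats(-5, 0), t=st.floats(0, 50), g0=st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_support_never_negative(self, zeta, r0, rs, rl, t, g0):
        ext = ReceptorExtension(enabled=True, zeta=zeta, R0=r0, R_stim=rs, R_loss=rl)
        assert ns.receptor_gain_support(ext, t, g0) >= 0.0


class TestIntegration:
    def test_zero_injury_fixed_point(self):
        zero = InjurySignal("constant", magnitude=0.0)
        traj = ns.integrate_trajectory(ALL_HALF, zero, zero, SHORTFALL, horizon=24.0)
        assert np.all(traj.N == ALL_HALF.N0)
        assert not traj.entrapped

    def test_constant_load_linear_decay(self):
        p = ALL_HALF
        I = InjurySignal("constant", magnitude=1.0)
        CI = InjurySignal("constant", magnitude=0.5)
        k = ns.behavioral_load(p, 1.0, 0.5) + ns.gain_collapse(p, 1.0, 0.5, SHORTFALL)
        traj = ns.integrate_trajectory(p, I, CI, SHORTFALL, horizon=2.0)
        expected = p.N0 - p.eta * k * traj.times
        np.testing.assert_allclose(traj.N, expected, atol=1e-12)

    def test_exp_decay_plateau_matches_quadrature(self):
        rng = np.random.default_rng(5)
        p = random_parameters(rng)
        I = InjurySignal("exp_decay", magnitude=1.5, tau=2.0)
        CI = InjurySignal("exp_decay", magnitude=0.5, tau=3.0)
        traj = ns.integrate_trajectory(p, I, CI, SHORTFALL, horizon=40.0)
        assert np.all(np.diff(traj.N) <= 1e-15)

        def load(t):
            return (ns.behavioral_load(p, I.evaluate(t), CI.evaluate(t))
                    + ns.gain_collapse(p, I.evaluate(t), CI.evaluate(t), SHORTFALL))

        total, _ = quad(load, 0, 40.0, limit=200)
        plateau = max(0.0, p.N0 - p.eta * total)
        assert traj.N[-1] == pytest.approx(plateau, abs=1e-7)

    def test_eta_linearity_of_preclamp_decline(self):
        rng = np.random.default_rng(1)
        p = random_parameters(rng).updated(eta=0.2)
        I = InjurySignal("exp_decay", magnitude=2.0, tau=3.0)
        CI = InjurySignal("constant", magnitude=0.3)
        t1 = ns.integrate_trajectory(p, I, CI, SHORTFALL, horizon=12.0)
        t2 = ns.integrate_trajectory(p.updated(eta=0.4), I, CI, SHORTFALL, horizon=12.0)
        d1 = p.eta * t1.cumulative_load
        d2 = 0.4 * t2.cumulative_load
        np.testing.assert_allclose(d2[1:], 2.0 * d1[1:], rtol=1e-9)

    def test_superposition_of_inputs(self):
        p = ALL_HALF
        i1 = InjurySignal("exp_decay", magnitude=1.0, tau=2.0)
        i2 = InjurySignal("constant", magnitude=0.4)
        c1 = InjurySignal("constant", magnitude=0.2)
        c2 = InjurySignal("exp_decay", magnitude=0.6, tau=5.0)
        # pre-clamp decline is additive because the load is affine in the inputs
        ta = ns.integrate_trajectory(p, i1, c1, SHORTFALL, horizon=10.0)
        tb = ns.integrate_trajectory(p, i2, c2, SHORTFALL, horizon=10.0)
        # combined run: evaluate loads of the summed inputs on the same grid
        la = p.eta * ta.cumulative_load
        lb = p.eta * tb.cumulative_load
        combined = (
            np.asarray(i1.integral(ta.times)) + np.asarray(i2.integral(ta.times)),
            np.asarray(c1.integral(ta.times)) + np.asarray(c2.integral(ta.times)),
        )
        k_i = p.behavioral_slope_I + p.psi * p.degradation_slope_I
        k_ci = p.behavioral_slope_CI + p.psi * p.degradation_slope_CI
        lsum = p.eta * (k_i * combined[0] + k_ci * combined[1])
        np.testing.assert_allclose(lsum, la + lb, rtol=1e-10, atol=1e-12)

    def test_piecewise_matches_clamped_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_parameters(rng).updated(eta=float(rng.uniform(0.3, 1.0)))
            bps = np.sort(rng.uniform(0.5, 9.5, size=2))
            levels = rng.uniform(0, 6, size=3)
            I = InjurySignal("piecewise_constant", breakpoints=tuple(bps), levels=tuple(levels))
            CI = InjurySignal("constant", magnitude=float(rng.uniform(0, 1)))
            traj = ns.integrate_trajectory(p, I, CI, SHORTFALL, horizon=10.0)
            k_i = p.behavioral_slope_I + p.psi * p.degradation_slope_I
            k_ci = p.behavioral_slope_CI + p.psi * p.degradation_slope_CI
            exact = np.clip(
                p.N0 - p.eta * (k_i * np.asarray(I.integral(traj.times))
                                + k_ci * np.asarray(CI.integral(traj.times))),
                SHORTFALL.N_floor, p.N0)
            np.testing.assert_allclose(traj.N, exact, atol=1e-8)

    @given(i0=st.floats(0, 5), c0=st.floats(0, 5), tau=st.floats(0.5, 10),
           seed=st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_shortfall_monotone_nonincreasing(self, i0, c0, tau, seed):
        p = random_parameters(np.random.default_rng(seed))
        I = InjurySignal("exp_decay", magnitude=i0, tau=tau)
        CI = InjurySignal("constant", magnitude=c0)
        traj = ns.integrate_trajectory(p, I, CI, SHORTFALL, horizon=12.0)
        assert np.all(np.diff(traj.N) <= 1e-12)
        assert np.all((traj.N >= SHORTFALL.N_floor - 1e-12) & (traj.N <= p.N0 + 1e-12))

    def test_literal_zero_injury_declines_at_psi_g0(self):
        zero = InjurySignal("constant", magnitude=0.0)
        p = ALL_HALF.updated(eta=0.2, psi=0.5, G0=1.0)
        traj = ns.integrate_trajectory(p, zero, zero, LITERAL, horizon=5.0)
        np.testing.assert_allclose(traj.N, 1.0 - 0.1 * traj.times, atol=1e-12)

    def test_receptor_relief_slows_decline(self):
        I = InjurySignal("exp_decay", magnitude=3.0, tau=3.0)
        CI = InjurySignal("constant", magnitude=0.5)
        ext = ReceptorExtension(enabled=True, zeta=0.8, R_stim=0.5)
        base = ns.integrate_trajectory(ALL_HALF, I, CI, SHORTFALL, horizon=12.0)
        helped = ns.integrate_trajectory(ALL_HALF, I, CI, SHORTFALL, ext=ext, horizon=12.0)
        assert helped.N[-1] >= base.N[-1]

    def test_bad_horizon_rejected(self):
        zero = InjurySignal("constant", magnitude=0.0)
        with pytest.raises(DomainError):
            ns.integrate_trajectory(ALL_HALF, zero, zero, SHORTFALL, horizon=0.0)


class TestEntrapment:
    def _linear_traj(self, rate=0.1, n0=1.0, horizon=10.0):
        times = np.arange(0.0, horizon + 0.05, 0.1)
        N = n0 - rate * times
        z = np.zeros_like(times)
        return ns.Trajectory(times=times, N=N, behavioral_load=z, gain_collapse=z,
                             total_load=z, cumulative_load=z)

    def test_constant_above_threshold(self):
        traj = self._linear_traj(rate=0.0)
        assert ns.classify_entrapment(traj, 0.3) == (False, None)

    def test_linear_decay_crossing_time(self):
        traj = self._linear_traj(rate=0.1)
        flag, t = ns.classify_entrapment(traj, 0.3)
        assert flag and t == pytest.approx(7.0, abs=1e-9)

    def test_touching_threshold_not_crossing(self):
        times = np.array([0.0, 1.0, 2.0])
        N = np.array([1.0, 0.3, 0.3])
        z = np.zeros(3)
        traj = ns.Trajectory(times, N, z, z, z, z)
        assert ns.classify_entrapment(traj, 0.3) == (False, None)

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            ns.classify_entrapment(self._linear_traj(), 1.5)


class TestModelConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(step=0.0)
        with pytest.raises(ConfigError):
            ModelConfig(entrapment_threshold=1.0)
        with pytest.raises(ConfigError):
            ModelConfig(collapse_convention="prose")

    def test_trajectory_frame_columns(self):
        zero = InjurySignal("constant", magnitude=0.0)
        traj = ns.integrate_trajectory(ALL_HALF, zero, zero, SHORTFALL, horizon=1.0)
        assert list(traj.to_frame().columns) == [
            "time_weeks", "N", "behavioral_load", "gain_collapse", "total_load"]
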