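"""Core model: covariate relations, closed-form kinetics, residual error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tacropk import (
    InfusionSegment,
    PKState,
    PopulationParameters,
    SubjectProfile,
    apply_residual_error,
    individual_parameters,
    propagate_state,
    simulate_profile,
)


class TestIndividualParameters:
    @pytest.mark.parametrize(
        "weight,inhibitor,expected_cl,expected_v1",
        [
            (70.0, 0, 4.2, 61.9),                      # reference patient
            (70.0, 1, 4.2 * 0.8, 61.9),                # inhibitor on CL only
            (7.0, 0, 4.2 * 0.1 ** 0.75, 6.19),         # allometric scaling
        ],
    )
    def test_covariate_model(self, pop, weight, inhibitor, expected_cl,
                             expected_v1):
        p = individual_parameters(pop, weight, inhibitor)
        assert p.cl == pytest.approx(expected_cl, rel=1e-12)
        assert p.v1 == pytest.approx(expected_v1, rel=1e-12)
        assert p.q == pytest.approx(p.cl * pop.fact, rel=1e-12)
        assert p.v2 == pytest.approx(p.v1 * pop.fact, rel=1e-12)

    def test_random_effects_enter_log_normally(self, pop):
        p = individual_parameters(pop, 23.9, 0, eta_cl=0.3, eta_v1=-0.2,
                                  kappa=0.1)
        base = individual_parameters(pop, 23.9, 0)
        assert p.cl == pytest.approx(base.cl * np.exp(0.4), rel=1e-12)
        assert p.v1 == pytest.approx(base.v1 * np.exp(-0.2), rel=1e-12)

    def test_monotone_in_weight(self, pop):
        cls = [individual_parameters(pop, w, 0).cl for w in (6, 23.9, 70, 150)]
        assert np.all(np.diff(cls) > 0)
        v1s = [individual_parameters(pop, w, 0).v1 for w in (6, 23.9, 70)]
        assert v1s[1] / v1s[0] == pytest.approx(23.9 / 6, rel=1e-12)

    def test_invalid_inputs(self, pop):
        with pytest.raises(ValueError):
            individual_parameters(pop, -5.0, 0)
        with pytest.raises(ValueError):
            individual_parameters(pop, 70.0, 2)


class TestPropagateState:
    def test_zero_input_zero_state(self, pop):
        p = individual_parameters(pop, 70, 0)
        s = propagate_state(PKState(), p, rate=0.0, dt=50.0)
        assert s.a1 == 0.0 and s.a2 == 0.0 and s.t == 50.0

    def test_steady_state_amounts(self, pop):
        p = individual_parameters(pop, 70, 0)
        s = propagate_state(PKState(), p, rate=87.5, dt=5000.0)
        assert s.a1 / p.v1 == pytest.approx(87.5 / p.cl, rel=1e-9)
        assert s.a2 / p.v2 == pytest.approx(87.5 / p.cl, rel=1e-9)

    def test_negative_dt_rejected(self, pop):
        p = individual_parameters(pop, 70, 0)
        with pytest.raises(ValueError):
            propagate_state(PKState(), p, rate=1.0, dt=-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.3, 15.0),
        v1=st.floats(3.0, 150.0),
        fact=st.floats(0.5, 4.0),
        rate=st.floats(0.0, 300.0),
        dt=st.floats(0.1, 120.0),
        a0=st.floats(0.0, 800.0),
    )
    def test_matches_ode_oracle(self, cl, v1, fact, rate, dt, a0):
        """Closed-form propagation equals adaptive ODE integration (1e-6)."""
        q, v2 = cl * fact, v1 * fact
        p_cls = type("P", (), dict(cl=cl, v1=v1, q=q, v2=v2))

        def odes(t, a):
            return [rate - (cl / v1) * a[0] - (q / v1) * a[0] + (q / v2) * a[1],
                    (q / v1) * a[0] - (q / v2) * a[1]]

        sol = solve_ivp(odes, (0, dt), [a0, a0 / 2], rtol=1e-10, atol=1e-10)
        s = propagate_state(PKState(a1=a0, a2=a0 / 2), p_cls, rate, dt)
        scale = max(1.0, abs(sol.y[0, -1]), abs(sol.y[1, -1]))
        assert abs(s.a1 - sol.y[0, -1]) / scale < 1e-6
        assert abs(s.a2 - sol.y[1, -1]) / scale < 1e-6


def _constant_regimen(rate, n_days=30):
    return tuple(InfusionSegment(24.0 * j, 24.0, rate) for j in range(n_days))


class TestSimulateProfile:
    def test_steady_state_trough_is_rate_over_cl(self, pop):
        p = individual_parameters(pop, 70, 0)
        subj = SubjectProfile(1, 70.0, regimen=_constant_regimen(87.5))
        c = simulate_profile(subj, p, [600.0])
        assert c[0] == pytest.approx(87.5 / p.cl, rel=1e-3)

    @pytest.mark.parametrize("fact", [1.0, 2.0, 4.0])
    def test_steady_state_independent_of_fact(self, fact):
        """Trough = rate/CL regardless of the peripheral-compartment link."""
        pop = PopulationParameters(fact=fact)
        p = individual_parameters(pop, 70, 0)
        subj = SubjectProfile(1, 70.0, regimen=_constant_regimen(87.5, 40))
        c = simulate_profile(subj, p, [900.0])
        assert c[0] == pytest.approx(87.5 / 4.2, rel=1e-4)

    def test_superposition_of_simultaneous_segments(self, pop):
        p = individual_parameters(pop, 23.9, 0)
        one = SubjectProfile(1, 23.9, regimen=(InfusionSegment(0, 72, 30.0),))
        two = SubjectProfile(1, 23.9, regimen=(
            InfusionSegment(0, 72, 15.0), InfusionSegment(0, 72, 15.0)))
        times = [5.0, 23.75, 47.75, 70.0]
        assert np.allclose(simulate_profile(one, p, times),
                           simulate_profile(two, p, times), rtol=1e-12)

    def test_segment_splitting_invariance(self, pop):
        p = individual_parameters(pop, 23.9, 0)
        whole = SubjectProfile(1, 23.9, regimen=(InfusionSegment(0, 24, 30.0),))
        split = SubjectProfile(1, 23.9, regimen=(
            InfusionSegment(0, 12, 30.0), InfusionSegment(12, 12, 30.0)))
        times = np.linspace(0.5, 24.0, 17)
        assert np.allclose(simulate_profile(whole, p, times),
                           simulate_profile(split, p, times), rtol=1e-10)

    def test_rate_change_matches_piecewise_ode_oracle(self, pop):
        """Rate doubled at day 3: closed-form matches the ODE solution."""
        p = individual_parameters(pop, 23.9, 0)
        subj = SubjectProfile(1, 23.9, regimen=(
            InfusionSegment(0, 72, 30.0), InfusionSegment(72, 72, 60.0)))
        times = [23.75, 71.75, 75.0, 95.75, 143.75]

        def odes(t, a):
            rate = 30.0 if t < 72 else 60.0
            return [rate - (p.cl / p.v1) * a[0] - (p.q / p.v1) * a[0]
                    + (p.q / p.v2) * a[1],
                    (p.q / p.v1) * a[0] - (p.q / p.v2) * a[1]]

        sol = solve_ivp(odes, (0, 144), [0, 0], rtol=1e-10, atol=1e-10,
                        t_eval=times, max_step=1.0)
        got = simulate_profile(subj, p, times)
        assert np.allclose(got, sol.y[0] / p.v1, rtol=1e-6)

    def test_time_before_first_dose_is_zero(self, pop):
        p = individual_parameters(pop, 23.9, 0)
        subj = SubjectProfile(1, 23.9,
                              regimen=(InfusionSegment(24, 24, 30.0),))
        c = simulate_profile(subj, p, [1.0, 10.0, 30.0])
        assert c[0] == 0.0 and c[1] == 0.0 and c[2] > 0.0

    def test_per_occasion_parameters(self, pop):
        """Clearance jumps between occasions change the profile continuously."""
        lo = individual_parameters(pop, 23.9, 0, kappa=-0.3)
        hi = individual_parameters(pop, 23.9, 0, kappa=0.3)
        subj = SubjectProfile(1, 23.9, regimen=_constant_regimen(30.0, 4),
                              occasion_breaks=(24.0, 48.0, 72.0))
        c = simulate_profile(subj, [lo, hi, lo, hi], [23.9, 24.1, 47.75])
        assert abs(c[1] - c[0]) < 0.15  # continuity across the boundary
        single = simulate_profile(
            SubjectProfile(1, 23.9, regimen=_constant_regimen(30.0, 4)),
            lo, [47.75])
        assert c[2] < single[0]  # higher CL on day 2 lowers the trough


class TestResidualError:
    def test_zero_noise_identity(self, rng):
        assert apply_residual_error(10.0, 0.0, rng) == 10.0

    def test_zero_concentration_stays_zero(self, rng):
        assert apply_residual_error(0.0, 0.5, rng) == 0.0

    def test_sample_cv_matches_sigma(self, rng):
        dv = apply_residual_error(np.full(100_000, 10.0), 0.179, rng)
        assert np.std(dv / 10.0 - 1.0) == pytest.approx(0.179, abs=0.004)
        assert np.all(dv >= 0.0)


class TestValidation:
    def test_population_parameters_invariants(self):
        with pytest.raises(ValueError):
            PopulationParameters(theta_cl=-1.0)
        with pytest.raises(ValueError):
            PopulationParameters(theta_inh=1.4)
        with pytest.raises(ValueError):
            PopulationParameters(sigma_prop=-0.1)

    def test_infusion_segment_invariants(self):
        with pytest.raises(ValueError):
            InfusionSegment(0.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            InfusionSegment(0.0, 24.0, -1.0)

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            SubjectProfile(1, -3.0)
        with pytest.raises(ValueError):
            SubjectProfile(1, 20.0, occasion_breaks=(48.0, 24.0))
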