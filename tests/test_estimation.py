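"""Estimation: MAP modes, marginal OFV approximations, population fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from tacropk import (
    CohortDesign,
    PopulationParameters,
    generate_cohort,
    map_estimate,
    marginal_ofv,
    sample_subjects,
    simulate_trial,
)
from tacropk.data import COLUMNS, PKEventDataset
from tacropk.estimation import (
    CovariateCandidate,
    build_panel,
    covariate_step,
    fit_population,
    map_estimates_panel,
    panel_predict,
)


def _subject_frame(sid, wt, rates, dvs, inh=0, tobs_offset=23.75):
    """Daily-bag event rows for one subject; dvs may contain None."""
    rows = []
    for j, rate in enumerate(rates):
        rows.append((sid, 24.0 * j, 1, rate * 24.0, rate, np.nan, 1, wt,
                     inh, j + 1))
        if dvs[j] is not None:
            rows.append((sid, 24.0 * j + tobs_offset, 0, np.nan, np.nan,
                         dvs[j], 0, wt, inh, j + 1))
    return pd.DataFrame(rows, columns=COLUMNS)


def _noise_free_dataset(pop, wt=23.9, n_days=14, eta_cl=0.0, eta_v1=0.0,
                        rates=None, sid=1):
    rates = rates if rates is not None else [1.25 * wt] * n_days
    panel_rows = _subject_frame(sid, wt, rates, [None] * n_days)
    ds = PKEventDataset(panel_rows)
    panel = build_panel(ds)
    f = panel_predict(panel, pop, np.array([eta_cl]), np.array([eta_v1]),
                      np.zeros((1, n_days)))[0]
    return PKEventDataset(_subject_frame(sid, wt, rates, list(f)))


class TestMapEstimate:
    def test_no_observations_returns_prior_mode(self, pop):
        frame = _subject_frame(1, 20.0, [25.0] * 3, [None] * 3)
        eta_cl, eta_v1, kap = map_estimate(PKEventDataset(frame), pop)
        assert eta_cl == 0.0 and eta_v1 == 0.0
        assert np.all(kap == 0.0)

    def test_recovers_known_effects_from_rich_noise_free_data(self):
        """Self-consistency: noise-free troughs pin down (η_CL, η_V1)."""
        pop = PopulationParameters(omega_cl=1.0, omega_v1=1.0, pi_cl=0.0,
                                   sigma_prop=0.01)
        # varying rates give the transient information that identifies V1
        rates = [30.0, 30.0, 45.0, 20.0, 35.0, 30.0, 40.0, 25.0, 30.0, 30.0,
                 30.0, 30.0, 30.0, 30.0]
        ds = _noise_free_dataset(pop, eta_cl=0.3, eta_v1=-0.2, rates=rates)
        eta_cl, eta_v1, kap = map_estimate(ds, pop)
        assert eta_cl == pytest.approx(0.3, abs=1e-3)
        assert eta_v1 == pytest.approx(-0.2, abs=1e-3)
        assert np.all(kap == 0.0)

    def test_high_trough_implies_low_clearance(self, pop):
        typ = _noise_free_dataset(pop, n_days=1)
        dv = typ.observations["DV"].iloc[0]
        high = PKEventDataset(_subject_frame(1, 23.9, [1.25 * 23.9],
                                             [2.0 * dv]))
        eta_cl, _, _ = map_estimate(high, pop)
        assert eta_cl < 0.0

    def test_gradient_norm_small_at_mode(self, pop, small_cohort):
        panel = build_panel(small_cohort)
        modes = map_estimates_panel(panel, pop, method="foce")
        assert modes.converged
        assert modes.grad_norm.max() < 1e-4 * (1 + np.abs(modes.h).max())


class TestMarginalOfv:
    def test_degenerate_limit_equals_extended_least_squares(self, pop,
                                                            small_cohort):
        """All variances → 0: OFV is the ELS objective of the typical model."""
        pop0 = pop.replace(omega_cl=0.0, omega_v1=0.0, pi_cl=0.0)
        panel = build_panel(small_cohort)
        S, J = panel.n_subjects, panel.n_days
        f = panel_predict(panel, pop0, np.zeros(S), np.zeros(S),
                          np.zeros((S, J)))
        v = pop0.sigma_prop ** 2 * f ** 2
        r = np.where(panel.obs, np.nan_to_num(panel.dv) - f, 0.0)
        els = float(np.where(panel.obs, r * r / v + np.log(2 * np.pi * v),
                             0.0).sum())
        got = marginal_ofv(small_cohort, pop0, method="foce")
        assert got == pytest.approx(els, abs=1e-6)

    def test_duplicating_subjects_doubles_ofv(self, pop, small_cohort):
        dup = small_cohort.frame.copy()
        dup["ID"] = dup["ID"] + 1000
        both = PKEventDataset(pd.concat([small_cohort.frame, dup],
                                        ignore_index=True))
        for method in ("foce", "quad"):
            one = marginal_ofv(small_cohort, pop, method=method)
            two = marginal_ofv(both, pop, method=method)
            assert two == pytest.approx(2.0 * one, abs=1e-6)

    def test_invariant_to_subject_order(self, pop, small_cohort):
        frame = small_cohort.frame
        ids = list(pd.unique(frame["ID"]))
        shuffled = pd.concat([frame[frame["ID"] == sid]
                              for sid in reversed(ids)], ignore_index=True)
        assert marginal_ofv(PKEventDataset(shuffled), pop) == pytest.approx(
            marginal_ofv(small_cohort, pop), abs=1e-6)

    @pytest.mark.parametrize("method", ["foce", "quad"])
    def test_against_quadrature_oracle_small_instance(self, method):
        """2 subjects × 2 troughs, (η_CL, η_V1) only: OFV within 0.5 of
        direct numerical integration of the marginal likelihood."""
        pop = PopulationParameters(pi_cl=0.0)
        frames = [
            _subject_frame(1, 20.0, [25.0, 25.0], [9.5, 11.0]),
            _subject_frame(2, 60.0, [75.0, 75.0], [13.0, 12.0]),
        ]
        ds = PKEventDataset(pd.concat(frames, ignore_index=True))
        panel = build_panel(ds)

        def subject_ofv_oracle(i):
            def integrand(e2, e1):
                f = panel_predict(panel, pop,
                                  np.full(panel.n_subjects, e1),
                                  np.full(panel.n_subjects, e2),
                                  np.zeros((panel.n_subjects,
                                            panel.n_days)))[i]
                obs = panel.obs[i]
                v = pop.sigma_prop ** 2 * f[obs] ** 2
                r = panel.dv[i, obs] - f[obs]
                loglik = -0.5 * np.sum(r * r / v + np.log(2 * np.pi * v))
                logprior = (-0.5 * (e1 / pop.omega_cl) ** 2
                            - np.log(pop.omega_cl * np.sqrt(2 * np.pi))
                            - 0.5 * (e2 / pop.omega_v1) ** 2
                            - np.log(pop.omega_v1 * np.sqrt(2 * np.pi)))
                return np.exp(loglik + logprior)

            val, _ = integrate.dblquad(integrand, -1.5, 1.5, -1.8, 1.8,
                                       epsabs=1e-12, epsrel=1e-9)
            return -2.0 * np.log(val)

        oracle = sum(subject_ofv_oracle(i) for i in range(2))
        got = marginal_ofv(ds, pop, method=method)
        assert got == pytest.approx(oracle, abs=0.5)


class TestFitPopulation:
    def test_noise_free_typical_value_regression(self, pop):
        """Variances fixed at 0, noise-free data: θ recovered to optimizer
        tolerance (deterministic nonlinear regression limit)."""
        truth = pop.replace(omega_cl=0.0, omega_v1=0.0, pi_cl=0.0,
                            sigma_prop=0.0)
        rng = np.random.default_rng(21)
        design = CohortDesign(n_subjects=12, n_days=6, seed=21)
        subjects = sample_subjects(design, rng)
        ds = simulate_trial(subjects, truth, design, rng)
        # sigma near its (zero) truth: a large fixed sigma would bias the
        # extended-least-squares optimum by O(sigma^2) via the ln f^2 term
        init = truth.replace(theta_cl=3.0, theta_v1=80.0, sigma_prop=1e-3)
        res = fit_population(
            ds, init=init, compute_se=False, method="foce",
            fixed={"fact", "exp_cl", "exp_v", "theta_inh", "omega_cl",
                   "omega_v1", "pi_cl", "sigma_prop"})
        assert res.estimates.theta_cl == pytest.approx(4.2, rel=2e-3)
        assert res.estimates.theta_v1 == pytest.approx(61.9, rel=2e-2)

    def test_small_cohort_parameter_recovery(self, pop, small_cohort):
        """Scaled-down end-to-end fit stays in the truth's neighbourhood."""
        res = fit_population(small_cohort, init=pop, compute_se=False,
                             maxiter=800)
        est = res.estimates
        assert est.theta_cl == pytest.approx(4.2, rel=0.15)
        assert est.theta_v1 == pytest.approx(61.9, rel=0.35)
        assert est.sigma_prop == pytest.approx(0.179, rel=0.40)
        assert res.convergence["n_fev"] > 50
        assert np.isfinite(res.ofv)

    def test_standard_errors_reported(self, pop, small_cohort):
        res = fit_population(
            small_cohort, init=pop, compute_se=True, maxiter=250,
            fixed={"fact", "exp_cl", "exp_v", "theta_inh", "omega_v1",
                   "pi_cl", "sigma_prop"})
        for name in ("theta_cl", "theta_v1", "omega_cl"):
            assert name in res.rse
            assert res.rse[name] > 0
            assert res.standard_errors[name] == pytest.approx(
                getattr(res.estimates, name) * res.rse[name] / 100, rel=1e-6)
        table = res.summary_table()
        assert "theta_CL" in table and "OFV" in table


class TestCovariateStep:
    def test_no_candidates_returns_base(self, pop, small_cohort):
        res = covariate_step(small_cohort, init=pop, candidates=(),
                             fixed=set(FIT_ALL) - {"theta_cl"}, maxiter=60)
        assert res.included == []

    def test_inhibitor_effect_detected(self, pop):
        """θ_inh = 0.8 in the generator: the INH covariate is retained."""
        design = CohortDesign(n_subjects=60, n_days=8,
                              inhibitor_sample_fraction=0.3, seed=31)
        ds = generate_cohort(design, pop, np.random.default_rng(31))
        base = pop.replace(theta_inh=1.0)
        res = covariate_step(
            ds, init=base,
            candidates=[CovariateCandidate("inh_on_cl", "INH", "binary")],
            fixed=set(FIT_ALL), maxiter=120)
        assert res.included == ["inh_on_cl"]
        assert res.final.covariate_estimates["inh_on_cl"] == pytest.approx(
            0.8, abs=0.1)


FIT_ALL = {"theta_cl", "theta_v1", "theta_inh", "fact", "exp_cl", "exp_v",
           "omega_cl", "omega_v1", "pi_cl", "sigma_prop"}
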