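"""Likelihood, posterior, Metropolis sampler, and MCMC diagnostics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import nerdsim as ns
from nerdsim import ConfigError, ContractError
from nerdsim.inference import (
    FitSpec, PosteriorSample, credible_intervals, effective_sample_size,
    estimate_noise_sd, fit_mcmc, gelman_rubin, information_criteria,
    posterior_predictive_check, predict_scores,
)
from nerdsim.priors import PriorSet, PriorSpec


def _sample_from_draws(draws, names=("x",)):
    c, n, k = draws.shape
    return PosteriorSample(
        param_names=tuple(names), draws=draws,
        log_post=np.zeros((c, n)), log_lik=np.zeros((c, n)),
        acceptance_rate=0.3, noise_sd=1.0,
    )


class TestLogLikelihood:
    def test_zero_residuals_closed_form(self, patient, priors, cfg, obs_model):
        """Exact predictions leave only the Gaussian normalization term."""
        pred = predict_scores(patient.params, patient, obs_model, cfg)
        perfect = dataclasses.replace(patient, scores=pred)
        s = 2.5
        ll = ns.log_likelihood(patient.params, perfect, obs_model, cfg, noise_sd=s)
        n = len(pred)
        assert ll == pytest.approx(-0.5 * n * np.log(2 * np.pi * s * s), abs=1e-10)

    def test_monotone_in_residual_magnitude(self, patient, cfg, obs_model):
        pred = predict_scores(patient.params, patient, obs_model, cfg)
        near = dataclasses.replace(patient, scores=pred + 1.0)
        far = dataclasses.replace(patient, scores=pred + 2.0)
        ll_near = ns.log_likelihood(patient.params, near, obs_model, cfg, noise_sd=3.0)
        ll_far = ns.log_likelihood(patient.params, far, obs_model, cfg, noise_sd=3.0)
        assert ll_far < ll_near

    def test_matches_density_summation_oracle(self, patient, cfg, obs_model):
        sd = estimate_noise_sd(patient, obs_model)
        pred = predict_scores(patient.params, patient, obs_model, cfg)
        oracle = float(np.sum(stats.norm.logpdf(patient.scores, loc=pred, scale=sd)))
        ll = ns.log_likelihood(patient.params, patient, obs_model, cfg)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_zero_noise_rejected(self, patient, cfg, obs_model):
        with pytest.raises(ConfigError):
            ns.log_likelihood(patient.params, patient, obs_model, cfg, noise_sd=0.0)


class TestLogPosterior:
    def test_flat_prior_equals_likelihood(self, patient, cfg, obs_model):
        flat = PriorSet({n: PriorSpec(n, 0.0, 1.0, 0.5, 1.0, 1.0)
                         for n in ("alpha", "eta", "rho")})
        lp = ns.log_posterior(patient.params, patient, flat, obs_model, cfg)
        ll = ns.log_likelihood(patient.params, patient, obs_model, cfg)
        assert lp == pytest.approx(ll, abs=1e-10)

    def test_boundary_candidate_rejected_by_contract(self, patient, priors, cfg, obs_model):
        bad = patient.params.updated(alpha=1.0)
        assert ns.log_posterior(bad, patient, priors, obs_model, cfg) == -np.inf

    def test_matches_prior_plus_likelihood_oracle(self, patient, priors, cfg, obs_model):
        free = ("alpha", "eta", "rho")
        lp = ns.log_posterior(patient.params, patient, priors, obs_model, cfg, free=free)
        oracle = sum(
            stats.beta.logpdf(getattr(patient.params, n),
                              priors[n].shape_a, priors[n].shape_b)
            for n in free
        ) + ns.log_likelihood(patient.params, patient, obs_model, cfg)
        assert lp == pytest.approx(oracle, abs=1e-10)


class TestFitMcmc:
    def test_deterministic_given_seed(self, patient, priors):
        spec = FitSpec(chains=2, iterations=400, seed=21)
        a = fit_mcmc(patient, priors, spec)
        b = fit_mcmc(patient, priors, spec)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draws_inside_unit_interval(self, fitted_sample):
        assert np.all((fitted_sample.pooled > 0) & (fitted_sample.pooled < 1))
        assert 0.0 < fitted_sample.acceptance_rate < 1.0

    def test_prior_recovery_with_uninformative_data(self, patient, priors):
        """A huge noise sd flattens the likelihood; the posterior is the prior."""
        spec = FitSpec(free_parameters=("eta",), chains=4, iterations=3000, seed=5)
        s = fit_mcmc(patient, priors, spec, noise_sd=1e7)
        assert s.posterior_mean()["eta"] == pytest.approx(0.2, abs=0.015)

    def test_single_parameter_recovery(self, priors):
        """With all other coefficients at truth, eta is recovered closely."""
        truth = priors.mean_parameters().updated(eta=0.26)
        pat = ns.synthesize_patient(seed=31, params=truth)
        spec = FitSpec(free_parameters=("eta",), chains=4, iterations=3000, seed=31)
        s = fit_mcmc(pat, priors, spec)
        assert s.posterior_mean()["eta"] == pytest.approx(0.26, abs=0.05)

    def test_degenerate_schedule_rejected(self, patient, priors):
        flat = dataclasses.replace(patient, schedule=np.array([0.0, 0.0]),
                                   scores=np.array([1.0, 1.0]))
        with pytest.raises(Exception):
            fit_mcmc(flat, priors, FitSpec(chains=2, iterations=100, seed=0))


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        one = rng.normal(0.5, 0.1, size=(1, 2000, 1)).clip(0.01, 0.99)
        draws = np.repeat(one, 4, axis=0)
        r = gelman_rubin(_sample_from_draws(draws))
        assert r["x"] == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_chains_diverge(self):
        a = np.full((1, 200, 1), 0.2) + np.random.default_rng(1).normal(0, 1e-4, (1, 200, 1))
        b = np.full((1, 200, 1), 0.8) + np.random.default_rng(2).normal(0, 1e-4, (1, 200, 1))
        r = gelman_rubin(_sample_from_draws(np.concatenate([a, b])))
        assert r["x"] > 10.0

    def test_single_chain_rejected(self):
        draws = np.random.default_rng(3).uniform(size=(1, 100, 1))
        with pytest.raises(ContractError):
            gelman_rubin(_sample_from_draws(draws))

    def test_matches_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(7)
        draws = rng.beta(2, 3, size=(4, 500, 1))
        ours = gelman_rubin(_sample_from_draws(draws))["x"]
        ref = float(az.rhat(draws[:, :, 0], method="split"))
        assert ours == pytest.approx(ref, abs=1e-6)


class TestCredibleIntervals:
    def test_uniform_draws_quantiles(self):
        rng = np.random.default_rng(4)
        draws = rng.uniform(size=(2, 20_000, 1))
        lo, hi = credible_intervals(_sample_from_draws(draws))["x"]
        assert lo == pytest.approx(0.025, abs=0.01)
        assert hi == pytest.approx(0.975, abs=0.01)

    def test_degenerate_draws(self):
        draws = np.full((2, 100, 1), 0.42)
        lo, hi = credible_intervals(_sample_from_draws(draws))["x"]
        assert (lo, hi) == (0.42, 0.42)

    def test_bounds_inside_draw_range(self, fitted_sample):
        for name, (lo, hi) in credible_intervals(fitted_sample).items():
            j = fitted_sample.param_names.index(name)
            col = fitted_sample.pooled[:, j]
            assert col.min() <= lo <= hi <= col.max()

    def test_invalid_level(self, fitted_sample):
        with pytest.raises(ConfigError):
            credible_intervals(fitted_sample, level=1.5)


class TestInformationCriteria:
    def test_arithmetic(self, patient):
        draws = np.full((2, 50, 3), 0.5)
        s = _sample_from_draws(draws, names=("a", "b", "c"))
        s.log_lik = np.full((2, 50), -20.0)
        pat13 = dataclasses.replace(patient, schedule=patient.schedule[:13],
                                    scores=patient.scores[:13])
        aic, bic = information_criteria(s, pat13)
        assert aic == pytest.approx(46.0)
        assert bic == pytest.approx(3 * np.log(13) + 40.0)

    def test_extra_parameter_penalized(self, patient):
        s3 = _sample_from_draws(np.full((2, 50, 3), 0.5), names=("a", "b", "c"))
        s4 = _sample_from_draws(np.full((2, 50, 4), 0.5), names=("a", "b", "c", "d"))
        s3.log_lik = s4.log_lik = np.full((2, 50), -20.0)
        a3, b3 = information_criteria(s3, patient)
        a4, b4 = information_criteria(s4, patient)
        assert a4 > a3 and b4 > b3


class TestPosteriorPredictive:
    def test_self_consistent_coverage(self, fitted_sample, patient):
        ppc = posterior_predictive_check(fitted_sample, patient, n_rep=300, seed=1)
        assert ppc.overall_coverage == pytest.approx(0.95, abs=0.08)

    def test_gross_misfit_detected(self, fitted_sample, patient):
        shifted = dataclasses.replace(
            patient, scores=np.clip(patient.scores + 6 * fitted_sample.noise_sd, 0, 100))
        ppc = posterior_predictive_check(fitted_sample, shifted, n_rep=300, seed=1)
        assert ppc.overall_coverage < 0.4

    def test_deterministic(self, fitted_sample, patient):
        a = posterior_predictive_check(fitted_sample, patient, n_rep=100, seed=9)
        b = posterior_predictive_check(fitted_sample, patient, n_rep=100, seed=9)
        np.testing.assert_array_equal(a.coverage_by_time, b.coverage_by_time)

    def test_small_n_rep_rejected(self, fitted_sample, patient):
        with pytest.raises(ConfigError):
            posterior_predictive_check(fitted_sample, patient, n_rep=10, seed=0)


class TestDiagnosticsBundle:
    def test_summary_contains_all_parameters(self, fitted_sample, patient):
        diag = ns.summarize_fit(fitted_sample, patient)
        for name in fitted_sample.param_names:
            assert name in diag.r_hat and name in diag.ess
            lo, hi = diag.intervals[name]
            assert lo <= diag.medians[name] <= hi
            assert diag.r_hat[name] >= 1.0 - 1e-6

    def test_ess_positive(self, fitted_sample):
        for v in effective_sample_size(fitted_sample).values():
            assert v > 50
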