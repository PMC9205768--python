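"""Bayesian Poisson MRCA timing: log posterior, quadrature oracle, MCMC,
bridge sampling, model comparison."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from twinclock.clock import LineageCounts
from twinclock.synthetic import GESTATION_YEARS
from twinclock.timing import (
    GridSpec,
    TimingConfig,
    age_in_years,
    compare_models,
    fit_mcmc,
    log_posterior,
    marginal_likelihood_bridge,
    case_study_config,
    posterior_quadrature,
)

NCPTG = LineageCounts(2, 89, 114, "ncptg")

# the conjugate worked case: point-mass times summing to 79.22 y of exposure
CONJUGATE = TimingConfig(counts=NCPTG, rate_prior_mean=1.71,
                         fixed_times=(0.7666, 40.766, 39.221))


def test_printed_ages_convert_to_years():
    assert age_in_years(39, 11, 26) == pytest.approx(39.9879, abs=1e-3)
    assert age_in_years(38, 5, 14) == pytest.approx(38.4550, abs=1e-3)
    assert GESTATION_YEARS == pytest.approx(0.7666, abs=1e-4)


class TestLogPosterior:
    def _config(self, mode="fixed_endpoint"):
        # sampling times chosen to make T_A = 40.766, T_B = 39.221 exactly
        return TimingConfig(
            counts=NCPTG, rate_prior_mean=1.71,
            sampling_age_a=40.766 - GESTATION_YEARS,
            sampling_age_b=39.221 - GESTATION_YEARS,
            t_mrca_prior_upper=37.766, post_mrca_interval_mode=mode)

    def test_out_of_support_is_minus_inf(self):
        cfg = self._config()
        assert log_posterior(2.0, -0.1, None, None, cfg) == -np.inf
        assert log_posterior(2.0, 38.0, None, None, cfg) == -np.inf
        assert log_posterior(-1.0, 1.0, None, None, cfg) == -np.inf

    def test_rate_truncation(self):
        cfg = TimingConfig(counts=NCPTG, rate_prior_mean=1.71,
                           rate_upper_bound=5.0)
        assert log_posterior(5.1, 1.0, 20.0, 20.0, cfg) == -np.inf
        assert np.isfinite(log_posterior(4.9, 1.0, 20.0, 20.0, cfg))

    def test_fixed_endpoint_matches_hand_summed_terms(self):
        cfg = self._config("fixed_endpoint")
        lam, tm = 2.0, 1.0
        expected = (
            stats.expon.logpdf(lam, scale=1.71)
            - math.log(37.766)
            + stats.poisson.logpmf(2, lam * tm)
            + stats.poisson.logpmf(89, lam * (40.766 - tm))
            + stats.poisson.logpmf(114, lam * (39.221 - tm))
        )
        assert log_posterior(lam, tm, None, None, cfg) == pytest.approx(expected)

    def test_latent_endpoint_adds_interval_priors(self):
        cfg = self._config("latent_endpoint")
        lam, tm, t1, t2 = 2.0, 1.0, 30.0, 25.0
        expected = (
            stats.expon.logpdf(lam, scale=1.71)
            - math.log(37.766)
            - math.log(40.766 - tm) - math.log(39.221 - tm)
            + stats.poisson.logpmf(2, lam * tm)
            + stats.poisson.logpmf(89, lam * (t1 - tm))
            + stats.poisson.logpmf(114, lam * (t2 - tm))
        )
        assert log_posterior(lam, tm, t1, t2, cfg) == pytest.approx(expected)
        # endpoints outside (t_mrca, T_i) are unsupported
        assert log_posterior(lam, tm, 0.5, t2, cfg) == -np.inf
        assert log_posterior(lam, tm, t1, 40.0, cfg) == -np.inf


class TestQuadrature:
    def test_conjugate_closed_form(self):
        # with all times fixed the rate posterior is
        # Gamma(1 + s + n_A + n_B, 1/mu + total exposure): mean 2.581
        q = posterior_quadrature(CONJUGATE)
        shape = 1 + 2 + 89 + 114
        rate = 1 / 1.71 + 79.2204
        assert q.means["lambda"] == pytest.approx(shape / rate, rel=1e-6)
        assert q.means["lambda"] == pytest.approx(2.581, abs=2e-3)
        lo, hi = q.intervals["lambda"]
        assert lo == pytest.approx(stats.gamma.ppf(0.025, shape, scale=1 / rate),
                                   rel=1e-3)
        assert hi == pytest.approx(stats.gamma.ppf(0.975, shape, scale=1 / rate),
                                   rel=1e-3)

    def test_conjugate_log_marginal_likelihood(self):
        q = posterior_quadrature(CONJUGATE)
        tm, t1, t2 = CONJUGATE.fixed_times
        s, na, nb = 2, 89, 114
        shape = 1 + s + na + nb
        rate = 1 / 1.71 + 79.2204
        closed = (-math.log(1.71) + s * math.log(tm)
                  + na * math.log(t1 - tm) + nb * math.log(t2 - tm)
                  - gammaln(s + 1) - gammaln(na + 1) - gammaln(nb + 1)
                  + gammaln(shape) - shape * math.log(rate))
        assert q.log_marginal_likelihood == pytest.approx(closed, abs=1e-6)

    def test_flat_likelihood_recovers_uniform_prior(self):
        # rate bounded near zero: the likelihood is flat and t_mrca keeps its
        # uniform prior, mean upper/2
        cfg = TimingConfig(counts=LineageCounts(0, 0, 0), rate_prior_mean=1.0,
                           rate_upper_bound=1e-4,
                           post_mrca_interval_mode="fixed_endpoint")
        q = posterior_quadrature(cfg)
        assert q.means["t_mrca"] == pytest.approx(cfg.t_upper / 2, rel=1e-3)

    def test_richardson_grid_refinement(self):
        cfg = case_study_config("ncptg")
        base = posterior_quadrature(cfg, GridSpec(n_lambda=300, n_t=600))
        fine = posterior_quadrature(cfg, GridSpec(n_lambda=600, n_t=1200))
        for k in ("lambda", "t_mrca"):
            assert base.means[k] == pytest.approx(fine.means[k], rel=1e-3)
        assert base.log_marginal_likelihood == pytest.approx(
            fine.log_marginal_likelihood, abs=5e-3)

    def test_posterior_mean_t_mrca_monotone_in_shared_count(self):
        means = []
        for s in range(0, 11):
            cfg = TimingConfig(counts=LineageCounts(s, 89, 114, "ncptg"),
                               rate_prior_mean=1.71)
            means.append(posterior_quadrature(cfg).means["t_mrca"])
        assert np.all(np.diff(means) > 0)

    def test_prior_sensitivity_bounded_by_interval_width(self):
        base = posterior_quadrature(case_study_config("ncptg"))
        doubled = posterior_quadrature(
            case_study_config("ncptg", rate_prior_mean=2 * 1.71))
        lo, hi = base.intervals["t_mrca"]
        assert abs(doubled.medians["t_mrca"] - base.medians["t_mrca"]) < hi - lo


class TestMcmc:
    def test_matches_quadrature_on_study_config(self):
        cfg = case_study_config("ncptg", chains=4, iters=8000, warmup=2000, seed=5)
        fit = fit_mcmc(cfg, compute_log_ml=False)
        q = posterior_quadrature(cfg)
        assert fit.mean("lambda") == pytest.approx(q.means["lambda"], rel=0.02)
        assert abs(fit.mean("t_mrca") - q.means["t_mrca"]) < 0.05
        assert (fit.summary["rhat"] < 1.01).all()

    def test_flat_likelihood_posterior_is_uniform(self):
        # Kolmogorov-Smirnov distance of pooled t_mrca draws to the uniform
        # prior below 0.02 at 10,000 draws
        cfg = TimingConfig(counts=LineageCounts(0, 0, 0), rate_prior_mean=1.0,
                           rate_upper_bound=1e-4,
                           post_mrca_interval_mode="fixed_endpoint",
                           chains=10, iters=14_000, warmup=4_000, seed=2)
        fit = fit_mcmc(cfg, compute_log_ml=False)
        draws = fit.draws["t_mrca"][:, ::10].reshape(-1)
        assert len(draws) == 10_000
        ks = stats.kstest(draws / cfg.t_upper, "uniform").statistic
        assert ks < 0.02

    def test_deterministic_under_seed(self):
        cfg = case_study_config("ncptg", post_mrca_interval_mode="fixed_endpoint",
                           chains=2, iters=2500, warmup=800, seed=7)
        a = fit_mcmc(cfg, compute_log_ml=False)
        b = fit_mcmc(cfg, compute_log_ml=False)
        assert np.array_equal(a.unconstrained, b.unconstrained)


class TestBridgeSampling:
    def test_agrees_with_conjugate_closed_form(self):
        cfg = TimingConfig(counts=NCPTG, rate_prior_mean=1.71,
                           fixed_times=(0.7666, 40.766, 39.221),
                           chains=4, iters=4000, warmup=1000, seed=3)
        fit = fit_mcmc(cfg)
        closed = posterior_quadrature(cfg).log_marginal_likelihood
        assert abs(fit.log_marginal_likelihood - closed) < 3 * fit.log_ml_se

    def test_reproducible_across_proposal_seeds(self):
        cfg = TimingConfig(counts=NCPTG, rate_prior_mean=1.71,
                           fixed_times=(0.7666, 40.766, 39.221),
                           chains=2, iters=5000, warmup=1000, seed=3)
        fit = fit_mcmc(cfg, compute_log_ml=False)
        flat = fit.unconstrained.reshape(-1, fit.unconstrained.shape[-1])
        ml1, se1 = marginal_likelihood_bridge(flat, cfg, seed=11)
        ml2, se2 = marginal_likelihood_bridge(flat, cfg, seed=99)
        assert abs(ml1 - ml2) < 3 * math.hypot(se1, se2)

    def test_needs_enough_draws(self):
        with pytest.raises(ValueError, match="4000"):
            marginal_likelihood_bridge(np.zeros((100, 2)), case_study_config("ncptg"))


class TestCompareModels:
    def test_identical_configs_give_zero_bayes_factor(self):
        cfg = case_study_config("ncptg")
        table = compare_models([cfg, cfg])
        assert table["log_bayes_factor_vs_first"].iloc[1] == pytest.approx(0.0)

    def test_fixed_vs_latent_endpoint_is_finite(self):
        table = compare_models([
            case_study_config("ncptg", post_mrca_interval_mode="latent_endpoint"),
            case_study_config("ncptg", post_mrca_interval_mode="fixed_endpoint"),
        ])
        assert np.isfinite(table["log_ml"]).all()
        assert table["log_bayes_factor_vs_first"].iloc[1] != 0.0

    def test_different_data_refused(self):
        with pytest.raises(ValueError, match="different data"):
            compare_models([case_study_config("ncptg"), case_study_config("all_clonal")])
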