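"""Likelihood identities, prior handling, sampler behavior, MAP and
posterior summaries -- exercised against cheap analytic stand-in
surrogates so the sampler itself is what is under test."""

import numpy as np
import pytest

from sasmc.inference import (MAPEstimate, PriorBox, SamplerConfig,
                             chi2_log_likelihood, log_posterior, map_estimate,
                             posterior_summary, run_mcmc, PosteriorSamples)
from sasmc.scattering import SAXSCurve, make_q_grid


class AnalyticSurrogate:
    """Stand-in emulator: smooth analytic curves I(q; z, k) (synthetic)."""

    def __init__(self, n_q=40):
        self.q = make_q_grid(0.012, 0.3, n_q)

    def predict_curve(self, params):
        theta = np.atleast_2d(np.asarray(params, dtype=float))
        z = theta[:, 0:1] / 40.0
        k = theta[:, 1:2] / 5.0
        x = self.q[None, :] / 0.3
        out = np.exp(-3.0 * z * x - 2.0 * k * x ** 2) + 0.05
        return out[0] if np.ndim(params) == 1 else out


@pytest.fixture(scope="module")
def surrogate():
    return AnalyticSurrogate()


@pytest.fixture(scope="module")
def data(surrogate):
    truth = np.array([35.0, 5.0])
    intensity = surrogate.predict_curve(truth)
    sigma = 0.02 * intensity
    return SAXSCurve(surrogate.q, intensity, sigma=sigma,
                     labels=tuple(truth))


class TestChiSquareLikelihood:
    def test_perfect_fit_is_zero(self, surrogate, data):
        assert chi2_log_likelihood(np.array(data.labels), data,
                                   surrogate) == pytest.approx(0.0, abs=1e-20)

    def test_doubling_sigma_quarters_the_deficit(self, surrogate, data):
        theta = np.array([30.0, 4.0])
        base = chi2_log_likelihood(theta, data, surrogate)
        wide = SAXSCurve(data.q, data.intensity, sigma=2.0 * data.sigma)
        assert chi2_log_likelihood(theta, wide, surrogate) == pytest.approx(
            base / 4.0, rel=1e-12)

    def test_one_sigma_residual_gives_minus_half(self, surrogate):
        truth = np.array([35.0, 5.0])
        base = surrogate.predict_curve(truth)
        shifted = SAXSCurve(surrogate.q[:1], base[:1] + 0.01,
                            sigma=np.array([0.01]))

        class OnePoint:
            q = surrogate.q[:1]

            def predict_curve(self, params):
                return base[:1] if np.ndim(params) == 1 \
                    else np.tile(base[:1], (np.atleast_2d(params).shape[0], 1))

        assert chi2_log_likelihood(truth, shifted, OnePoint()) \
            == pytest.approx(-0.5, rel=1e-10)

    def test_default_fractional_sigma_when_absent(self, surrogate, data):
        bare = SAXSCurve(data.q, data.intensity)
        theta = np.array([30.0, 4.0])
        assert chi2_log_likelihood(theta, bare, surrogate) == pytest.approx(
            chi2_log_likelihood(theta, data, surrogate), rel=1e-12)


class TestLogPosterior:
    def test_outside_box_is_minus_infinity(self, surrogate, data):
        assert log_posterior(np.array([5.0, 5.0]), data, surrogate) == -np.inf
        assert log_posterior(np.array([40.0, 9.0]), data, surrogate) == -np.inf

    def test_boundary_is_inside_the_closed_box(self, surrogate, data):
        assert np.isfinite(log_posterior(np.array([70.0, 7.0]), data,
                                         surrogate))
        assert np.isfinite(log_posterior(np.array([10.0, 3.0]), data,
                                         surrogate))

    def test_interior_ranking_matches_likelihood(self, surrogate, data):
        zs = np.linspace(10, 70, 41)
        ks = np.linspace(3, 7, 31)
        grid = np.array([(z, k) for z in zs for k in ks])
        lp = log_posterior(grid, data, surrogate)
        ll = chi2_log_likelihood(grid, data, surrogate)
        assert np.argmax(lp) == np.argmax(ll)


class TestSampler:
    def test_flat_likelihood_recovers_the_prior(self, surrogate, data):
        """sigma -> infinity: the posterior must reduce to the uniform prior."""
        from scipy.stats import kstest
        flat = SAXSCurve(data.q, data.intensity,
                         sigma=1e9 * data.intensity)
        # thin at the step level to roughly independent ensemble draws
        post = run_mcmc(flat, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=4000,
                                             thin=60, seed=1))
        z = post.samples[:, 0]
        k = post.samples[:, 1]
        assert kstest(z, "uniform", args=(10.0, 60.0)).pvalue > 0.01
        assert kstest(k, "uniform", args=(3.0, 4.0)).pvalue > 0.01

    def test_peaked_likelihood_centers_on_truth(self, surrogate, data):
        post = run_mcmc(data, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=1500,
                                             seed=2))
        mean = post.samples.mean(axis=0)
        sd = post.samples.std(axis=0)
        assert abs(mean[0] - 35.0) < 3.0 * sd[0] + 0.5
        assert abs(mean[1] - 5.0) < 3.0 * sd[1] + 0.05

    def test_no_sample_ever_leaves_the_prior_box(self, surrogate, data):
        post = run_mcmc(data, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=800,
                                             seed=3))
        assert np.all(PriorBox().contains(post.samples))

    def test_seed_reproducibility_and_chain_bookkeeping(self, surrogate, data):
        cfg = SamplerConfig(n_walkers=16, n_steps=600, seed=5)
        a = run_mcmc(data, surrogate, config=cfg)
        b = run_mcmc(data, surrogate, config=cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        expected = 16 * (600 - int(0.2 * 600))
        assert a.samples.shape == (expected, 2)

    def test_independent_seeds_agree_within_mc_error(self, surrogate, data):
        cfg1 = SamplerConfig(n_walkers=16, n_steps=1200, seed=11)
        cfg2 = SamplerConfig(n_walkers=16, n_steps=1200, seed=12)
        m1 = run_mcmc(data, surrogate, config=cfg1).samples.mean(axis=0)
        m2 = run_mcmc(data, surrogate, config=cfg2).samples.mean(axis=0)
        assert abs(m1[0] - m2[0]) < 1.5
        assert abs(m1[1] - m2[1]) < 0.15


class TestMAP:
    def test_map_dominates_every_retained_sample(self, surrogate, data):
        post = run_mcmc(data, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=800,
                                             seed=7))
        est = map_estimate(post)
        assert est.log_posterior >= post.log_posterior.max()

    def test_map_inside_68_interval_for_unimodal_posterior(self, surrogate,
                                                           data):
        post = run_mcmc(data, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=1200,
                                             seed=8))
        est = map_estimate(post, data=data, surrogate=surrogate, refine=True)
        lo, hi = est.credible_intervals["z_eff"][68]
        assert lo <= est.z_eff <= hi
        lo, hi = est.credible_intervals["kappa_inv"][68]
        assert lo <= est.kappa_inv <= hi

    def test_refinement_never_worsens_the_map(self, surrogate, data):
        post = run_mcmc(data, surrogate,
                        config=SamplerConfig(n_walkers=16, n_steps=800,
                                             seed=9))
        plain = map_estimate(post)
        refined = map_estimate(post, data=data, surrogate=surrogate,
                               refine=True)
        assert refined.log_posterior >= plain.log_posterior

    def test_small_chain_rejected(self):
        tiny = PosteriorSamples(samples=np.zeros((10, 2)),
                                log_posterior=np.zeros(10), n_walkers=8,
                                n_steps=10, burn_in=0, thin=1, seed=0)
        with pytest.raises(ValueError):
            map_estimate(tiny)


class TestPosteriorSummary:
    def test_independent_samples_have_near_zero_correlation(self):
        rng = np.random.default_rng(0)
        post = PosteriorSamples(
            samples=np.column_stack([rng.uniform(10, 70, 20000),
                                     rng.uniform(3, 7, 20000)]),
            log_posterior=np.zeros(20000), n_walkers=8, n_steps=2500,
            burn_in=0, thin=1, seed=0)
        summary = posterior_summary(post, prior=PriorBox())
        assert abs(summary.correlation) < 0.05

    def test_marginal_histograms_integrate_to_one(self):
        rng = np.random.default_rng(1)
        post = PosteriorSamples(
            samples=np.column_stack([rng.normal(40, 5, 5000),
                                     rng.normal(5, 0.5, 5000)]),
            log_posterior=np.zeros(5000), n_walkers=8, n_steps=625,
            burn_in=0, thin=1, seed=0)
        s = posterior_summary(post, prior=PriorBox())
        assert np.sum(s.density_z * np.diff(s.edges_z)) == pytest.approx(1.0)
        assert np.sum(s.density_k * np.diff(s.edges_k)) == pytest.approx(1.0)
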