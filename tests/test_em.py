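"""EM correctness: monotone traces, parameter recovery, BIC order selection."""

import numpy as np
import pytest
from scipy.special import gammaln

from jcmflow import (ComponentParams, FitOptions, MixtureModel, bic_score,
                     fit_mixture, initialize_mixture, kl_divergence_mc,
                     parameter_count, posterior_responsibilities, sample_mixture,
                     select_components, update_parameters)
from jcmflow.distributions import LatentAugmentation, log_mixture_pdf


def assert_monotone(trace, tol=1e-8):
    diffs = np.diff(trace)
    assert np.all(diffs >= -tol), f"log-likelihood decreased by {-diffs.min():.2e}"


class TestInitialization:
    def test_separated_blobs_recover_centers(self, rng):
        centers = np.array([[0.0, 0.0], [8.0, 8.0]])
        Y = np.vstack([rng.normal(c, 0.5, size=(400, 2)) for c in centers])
        model = initialize_mixture(Y, g=2, family="t", seed=0)
        mus = sorted([c.mu for c in model.components], key=lambda m: m[0])
        for mu, c in zip(mus, centers):
            assert np.linalg.norm(mu - c) < 0.5

    def test_single_component_is_sample_moments(self, rng):
        Y = rng.normal(size=(300, 3))
        model = initialize_mixture(Y, g=1, family="t", seed=0)
        np.testing.assert_allclose(model.components[0].mu, Y.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(model.components[0].Sigma, np.cov(Y.T), rtol=1e-4)

    def test_deterministic(self, rng):
        Y = rng.normal(size=(500, 2))
        m1 = initialize_mixture(Y, g=3, family="t", seed=7)
        m2 = initialize_mixture(Y, g=3, family="t", seed=7)
        for c1, c2 in zip(m1.components, m2.components):
            np.testing.assert_array_equal(c1.mu, c2.mu)

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="smaller g"):
            initialize_mixture(np.zeros((5, 3)), g=2, family="t", seed=0)


class TestResponsibilities:
    def test_single_component_all_one(self, rng, t_mixture_1d):
        solo = MixtureModel("t", [t_mixture_1d.components[0]], ["x"])
        solo.components[0].pi = 1.0
        lat = posterior_responsibilities(rng.normal(size=(50, 1)), solo)
        np.testing.assert_allclose(lat.tau, 1.0)

    def test_symmetric_midpoint(self):
        comps = [ComponentParams(0.5, np.array([-2.0]), np.array([[1.0]]), np.zeros(1), 5.0),
                 ComponentParams(0.5, np.array([2.0]), np.array([[1.0]]), np.zeros(1), 5.0)]
        model = MixtureModel("t", comps, ["x"])
        lat = posterior_responsibilities(np.array([[0.0]]), model)
        np.testing.assert_allclose(lat.tau, [[0.5, 0.5]], atol=1e-12)

    def test_rows_normalize(self, rng, t_mixture_2d):
        Y = rng.normal(size=(200, 2)) * 4
        lat = posterior_responsibilities(Y, t_mixture_2d)
        np.testing.assert_allclose(lat.tau.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(lat.w > 0)

    def test_labels_match_brute_force_posterior(self, rng, t_mixture_2d):
        from jcmflow.distributions import log_mvt_pdf
        Y = rng.normal(size=(100, 2)) * 5
        lat = posterior_responsibilities(Y, t_mixture_2d)
        labels = np.argmax(lat.tau, axis=1)
        # brute force: direct per-component density ratios
        direct = np.column_stack([
            np.log(c.pi) + log_mvt_pdf(Y, c) for c in t_mixture_2d.components])
        np.testing.assert_array_equal(labels, np.argmax(direct, axis=1))


class TestUpdates:
    def test_gaussian_reduction(self, rng):
        # with w == 1 and zero skew, the M-step must equal the weighted
        # Gaussian formulas
        Y = rng.normal(size=(400, 2))
        model = initialize_mixture(Y, g=2, family="t", seed=1)
        tau = rng.dirichlet(np.ones(2), size=400)
        lat = LatentAugmentation(tau=tau, w=np.ones((400, 2)))
        opts = FitOptions(family="t", g=2, nu_mode="fixed:4")
        new = update_parameters(Y, lat, model, opts)
        for h, c in enumerate(new.components):
            th = tau[:, h]
            mu = (th[:, None] * Y).sum(axis=0) / th.sum()
            np.testing.assert_allclose(c.mu, mu, rtol=1e-10)
            R = Y - mu
            np.testing.assert_allclose(c.Sigma, (th[:, None] * R).T @ R / th.sum(),
                                       rtol=1e-6)
            assert c.pi == pytest.approx(th.mean())
            assert c.nu == 4.0

    def test_update_moves_toward_truth(self, t_mixture_2d):
        Y, _ = sample_mixture(t_mixture_2d, 50_000, seed=2)
        # perturb the truth, then one EM step from the perturbed model
        start = t_mixture_2d.copy()
        for c in start.components:
            c.mu = c.mu + 0.5
        lat = posterior_responsibilities(Y, start)
        new = update_parameters(Y, lat, start, FitOptions(family="t", g=2))
        for c_new, c_start, c_true in zip(new.components, start.components,
                                          t_mixture_2d.components):
            assert (np.linalg.norm(c_new.mu - c_true.mu)
                    < np.linalg.norm(c_start.mu - c_true.mu))


class TestFitMixture:
    def test_recovery_1d_two_components(self, t_mixture_1d):
        Y, _ = sample_mixture(t_mixture_1d, 5000, seed=3)
        fit = fit_mixture(Y, FitOptions(family="t", g=2, n_starts=3, seed=4))
        order = np.argsort([c.mu[0] for c in fit.model.components])
        pis = fit.model.pi[order]
        mus = np.array([fit.model.components[h].mu[0] for h in order])
        np.testing.assert_allclose(pis, [0.3, 0.7], atol=0.02)
        np.testing.assert_allclose(mus, [-3.0, 3.0], atol=0.1)
        assert_monotone(fit.loglik_trace)

    def test_g1_mean_is_sample_mean(self, rng):
        Y = rng.normal(size=(2000, 2))
        fit = fit_mixture(Y, FitOptions(family="t", g=1, seed=5, n_starts=1))
        # nearly Gaussian data: nu large, weighted mean converges to the mean
        np.testing.assert_allclose(fit.model.components[0].mu, Y.mean(axis=0), atol=1e-3)
        assert_monotone(fit.loglik_trace)

    def test_permutation_invariance(self, t_mixture_1d, rng):
        Y, _ = sample_mixture(t_mixture_1d, 1000, seed=6)
        fit = fit_mixture(Y, FitOptions(family="t", g=2, seed=7, n_starts=1))
        swapped = MixtureModel("t", fit.model.components[::-1], fit.model.marker_names)
        from jcmflow.em import _observed_loglik
        ll1, _ = _observed_loglik(Y, fit.model)
        ll2, _ = _observed_loglik(Y, swapped)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_skewt_fit_monotone_and_density_close(self):
        # construction consistency: the fitted skew-t mixture's density
        # approaches the generating one (raw skew parameters are only
        # weakly identified, so compare models by KL)
        comps = [ComponentParams(0.5, np.array([0.0]), np.array([[1.0]]),
                                 np.array([1.5]), 8.0),
                 ComponentParams(0.5, np.array([7.0]), np.array([[1.0]]),
                                 np.array([-1.0]), 8.0)]
        truth = MixtureModel("skew-t", comps, ["x"])
        Y, _ = sample_mixture(truth, 2000, seed=8)
        fit = fit_mixture(Y, FitOptions(family="skew-t", g=2, seed=9, n_starts=2,
                                        max_iter=200))
        assert_monotone(fit.loglik_trace)
        kl, se = kl_divergence_mc(truth, fit.model, n_mc=40_000, seed=10)
        assert kl < 0.05 + 3 * se


class TestBIC:
    def test_arithmetic(self):
        assert bic_score(-100.0, 5, 100) == pytest.approx(200 + 5 * np.log(100))

    def test_penalty_step(self):
        assert (bic_score(-50.0, 6, 200) - bic_score(-50.0, 5, 200)
                == pytest.approx(np.log(200)))

    def test_parameter_count(self):
        # g=2, p=3, t family: 1 proportion + 6 means + 12 scale + 2 dof
        assert parameter_count("t", 2, 3) == 21
        assert parameter_count("skew-t", 2, 3) == 27


class TestSelectComponents:
    def test_three_component_data_selects_three(self):
        comps = [ComponentParams(1 / 3, mu, np.eye(2), np.zeros(2), 8.0)
                 for mu in (np.array([0.0, 0.0]), np.array([7.0, 0.0]),
                            np.array([0.0, 7.0]))]
        truth = MixtureModel("t", comps, ["a", "b"])
        chosen = []
        for seed in range(10):
            Y, _ = sample_mixture(truth, 1200, seed=100 + seed)
            fit = select_components(Y, (1, 4), FitOptions(
                family="t", g=1, seed=seed, n_starts=1, tol=1e-5, max_iter=200))
            chosen.append(fit.model.g)
        assert np.mean(np.array(chosen) == 3) >= 0.8

    def test_single_blob_selects_one(self, rng):
        Y = rng.normal(size=(1500, 2))
        fit = select_components(Y, (1, 3), FitOptions(family="t", g=1, seed=11,
                                                      n_starts=1, tol=1e-5))
        assert fit.model.g == 1

    def test_degenerate_range(self, t_mixture_1d):
        Y, _ = sample_mixture(t_mixture_1d, 800, seed=12)
        fit = select_components(Y, (2, 2), FitOptions(family="t", g=2, seed=13,
                                                      n_starts=1))
        assert fit.model.g == 2

    def test_invalid_range(self, rng):
        with pytest.raises(ValueError, match=r"\[1, 30\]"):
            select_components(rng.normal(size=(100, 1)), (0, 2), FitOptions())


class TestNuHandling:
    def test_fixed_nu_respected(self, t_mixture_1d):
        Y, _ = sample_mixture(t_mixture_1d, 1500, seed=14)
        fit = fit_mixture(Y, FitOptions(family="t", g=2, seed=15, n_starts=1,
                                        nu_mode="fixed:4"))
        assert all(c.nu == 4.0 for c in fit.model.components)

    def test_gaussian_data_hits_nu_ceiling(self, rng):
        Y = rng.normal(size=(4000, 1))
        fit = fit_mixture(Y, FitOptions(family="t", g=1, seed=16, n_starts=1))
        assert fit.model.components[0].nu > 50  # effectively Gaussian
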