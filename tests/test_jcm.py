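"""Two-level model: transforms, registration, shrinkage, feature export."""

import numpy as np
import pytest

from jcmflow import (BatchSpec, FitOptions, JCMOptions, MarkerSample,
                     REMVariances, SampleBatch, SampleTransform,
                     default_template, estimate_transform,
                     export_feature_matrix, fit_jcm, fit_mixture,
                     misclassification_rate, sample_mixture, simulate_batch,
                     sample_model_from_template)


@pytest.fixture(scope="module")
def template3():
    return default_template(p=3, g=3, family="t", separation=4.0, seed=42)


class TestSampleModel:
    def test_identity_transform(self, template3):
        tr = SampleTransform.identity(3, 3, template3.pi)
        model = sample_model_from_template(template3, tr)
        for cm, ct in zip(model.components, template3.components):
            np.testing.assert_array_equal(cm.mu, ct.mu)
            np.testing.assert_array_equal(cm.Sigma, ct.Sigma)
            assert cm.pi == pytest.approx(ct.pi)

    def test_translation_single_entry(self, template3):
        tr = SampleTransform.identity(3, 3, template3.pi)
        tr.b[1, 2] = 2.0
        model = sample_model_from_template(template3, tr)
        diff = model.components[1].mu - template3.components[1].mu
        np.testing.assert_allclose(diff, [0.0, 0.0, 2.0])
        np.testing.assert_array_equal(model.components[0].mu, template3.components[0].mu)

    def test_scaling_arithmetic(self):
        tpl = default_template(p=2, g=1, family="t", seed=0)
        tpl.components[0].mu = np.array([2.0, -4.0])
        tr = SampleTransform(a=np.full((1, 2), 1.5), b=np.zeros((1, 2)),
                             pi=np.array([1.0]))
        model = sample_model_from_template(tpl, tr)
        np.testing.assert_allclose(model.components[0].mu, [3.0, -6.0])


class TestFitJCM:
    def test_single_sample_zero_variance_equals_mixture_fit(self, template3):
        # degenerate reduction: one sample, REM variances pinned at zero,
        # the two-level fit must coincide with the plain mixture fit
        Y, _ = sample_mixture(template3, 2000, seed=1)
        batch = SampleBatch("c", [MarkerSample("s1", template3.marker_names, Y)])
        jopt = JCMOptions(family="t", g=3, seed=2, n_starts=2,
                          sigma_a2=0.0, sigma_b2=0.0)
        jfit = fit_jcm(batch, jopt)
        sfit = fit_mixture(Y, FitOptions(family="t", g=3, seed=2, n_starts=2))
        assert jfit.total_loglik == pytest.approx(sfit.loglik, abs=1e-6)
        np.testing.assert_allclose(jfit.transforms[0].a, 1.0)
        np.testing.assert_allclose(jfit.transforms[0].b, 0.0)

    def test_recovery_with_translation_effects(self, template3):
        batch, truth = simulate_batch(BatchSpec(
            template=template3, m=8, n_per_sample=1500, sigma_a=0.0,
            sigma_b=0.3, seed=3))
        fit = fit_jcm(batch, JCMOptions(family="t", g=3, seed=4, n_starts=2))
        assert np.all(np.diff(fit.total_loglik_trace) >= -1e-6)
        mcrs = [misclassification_rate(ps.labels, truth.labels[k])
                for k, ps in enumerate(fit.per_sample)]
        assert np.mean(mcrs) < 0.05
        # match fitted to true components by nearest means
        from scipy.optimize import linear_sum_assignment
        true_mu = np.stack([c.mu for c in template3.components])
        est_mu = np.stack([c.mu for c in fit.template.components])
        D = np.linalg.norm(true_mu[:, None] - est_mu[None, :], axis=2)
        rows, cols = linear_sum_assignment(D)
        assert np.max(np.abs(true_mu[rows] - est_mu[cols])) < 0.35

    def test_identical_copies_give_identity_transforms(self, template3):
        Y, _ = sample_mixture(template3, 1500, seed=5)
        samples = [MarkerSample(f"s{k}", template3.marker_names, Y.copy())
                   for k in range(3)]
        batch = SampleBatch("c", samples)
        fit = fit_jcm(batch, JCMOptions(family="t", g=3, seed=6, n_starts=2))
        for tr in fit.transforms:
            assert np.max(np.abs(tr.a - 1.0)) < 0.02
            assert np.max(np.abs(tr.b)) < 0.02
        single = fit_mixture(Y, FitOptions(family="t", g=3, seed=6, n_starts=2))
        assert fit.total_loglik == pytest.approx(3 * single.loglik, rel=1e-3)

    def test_sample_too_small(self, template3):
        batch = SampleBatch("c", [MarkerSample("tiny", template3.marker_names,
                                               np.zeros((5, 3)))])
        with pytest.raises(ValueError, match="tiny"):
            fit_jcm(batch, JCMOptions(family="t", g=3))

    def test_registration_key_property(self, template3):
        # the sample model's means equal a*mu + b exactly by construction
        batch, _ = simulate_batch(BatchSpec(template=template3, m=2,
                                            n_per_sample=600, sigma_b=0.2, seed=7))
        fit = fit_jcm(batch, JCMOptions(family="t", g=3, seed=8, n_starts=1,
                                        max_iter=60))
        for k in range(2):
            model_k = fit.sample_model(k)
            for h, c in enumerate(model_k.components):
                expect = fit.transforms[k].a[h] * fit.template.components[h].mu \
                    + fit.transforms[k].b[h]
                np.testing.assert_allclose(c.mu, expect, rtol=1e-12)


class TestEstimateTransform:
    def test_null_transform_recovery(self, template3):
        Y, _ = sample_mixture(template3, 5000, seed=9)
        sample = MarkerSample("s", template3.marker_names, Y)
        tr, labels, ll = estimate_transform(sample, template3, REMVariances(0.1, 0.1))
        # the identified quantity is the combined mean shift a*mu + b - mu;
        # its sampling SE per component is ~ sd/sqrt(n/g) ~ 0.025 here.  The
        # a/b split itself is prior-dominated, so bound it more loosely.
        mu = np.stack([c.mu for c in template3.components])
        shift = tr.a * mu + tr.b - mu
        assert np.max(np.abs(shift)) < 0.075
        assert np.max(np.abs(tr.a - 1.0)) < 0.1
        assert np.max(np.abs(tr.b)) < 0.1
        assert labels.min() >= 1 and labels.max() <= 3

    def test_shift_recovery(self, template3):
        Y, lab = sample_mixture(template3, 5000, seed=10)
        Y = Y.copy()
        Y[lab == 1, 0] += 2.0    # shift marker 1 of population 2 only
        sample = MarkerSample("s", template3.marker_names, Y)
        tr, _, _ = estimate_transform(sample, template3,
                                      REMVariances(1e-6, 1.0),
                                      JCMOptions(translation_only=True))
        assert tr.b[1, 0] == pytest.approx(2.0, abs=0.1)
        others = np.delete(tr.b.ravel(), 1 * 3 + 0)
        assert np.max(np.abs(others)) < 0.1

    def test_scale_recovery(self):
        tpl = default_template(p=2, g=2, family="t", separation=5.0, seed=11)
        tr_true = SampleTransform(a=np.full((2, 2), 1.5), b=np.zeros((2, 2)),
                                  pi=tpl.pi)
        Y, _ = sample_mixture(sample_model_from_template(tpl, tr_true), 5000, seed=12)
        sample = MarkerSample("s", tpl.marker_names, Y)
        tr, _, _ = estimate_transform(sample, tpl, REMVariances(1.0, 1e-6))
        big = np.abs(np.stack([c.mu for c in tpl.components])) >= 1.0
        assert np.max(np.abs(tr.a[big] - 1.5)) < 0.1

    def test_marker_mismatch(self, template3):
        sample = MarkerSample("s", ["X", "Y", "Z"], np.zeros((10, 3)))
        with pytest.raises(ValueError, match="marker mismatch"):
            estimate_transform(sample, template3, REMVariances(0.1, 0.1))


class TestFeatureMatrix:
    def _small_fit(self):
        tpl = default_template(p=2, g=2, family="t", separation=4.0, seed=13)
        batch, _ = simulate_batch(BatchSpec(template=tpl, m=3, n_per_sample=400,
                                            sigma_b=0.1, seed=14))
        return fit_jcm(batch, JCMOptions(family="t", g=2, seed=15, n_starts=1,
                                         max_iter=50))

    def test_row_count_and_names(self):
        fit = self._small_fit()
        table = export_feature_matrix([fit])
        assert table.shape == (24, 3)       # 2*(1+2+2+2+1+2+2) rows
        assert "mu.1.M1" in table.index and "nu.2" in table.index

    def test_identity_transform_rows(self, template3):
        Y, _ = sample_mixture(template3, 1200, seed=16)
        batch = SampleBatch("c", [MarkerSample("s1", template3.marker_names, Y)])
        fit = fit_jcm(batch, JCMOptions(family="t", g=3, seed=17, n_starts=1,
                                        sigma_a2=0.0, sigma_b2=0.0))
        table = export_feature_matrix([fit])
        a_rows = table.loc[[r for r in table.index if r.startswith("a.")]]
        b_rows = table.loc[[r for r in table.index if r.startswith("b.")]]
        assert np.all(a_rows.values == 1.0)
        assert np.all(b_rows.values == 0.0)

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd
        fit = self._small_fit()
        table = export_feature_matrix([fit])
        path = tmp_path / "fm.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.values, table.values, rtol=1e-12)

    def test_inconsistent_shapes_rejected(self):
        fit = self._small_fit()
        tpl = default_template(p=3, g=2, family="t", seed=18)
        batch, _ = simulate_batch(BatchSpec(template=tpl, m=1, n_per_sample=300, seed=19))
        other = fit_jcm(batch, JCMOptions(family="t", g=2, seed=20, n_starts=1,
                                          max_iter=30))
        with pytest.raises(ValueError, match="same g and p"):
            export_feature_matrix([fit, other])
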