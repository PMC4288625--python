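"""Feature selection, metagene factorization and the probit Gibbs sampler."""

import numpy as np
import pytest
from scipy.special import ndtr

from bprsig import (ExpressionMatrix, McmcConfig, SignatureModel, factorize,
                    fit_bpr, project, select_features)
from bprsig.signature import _draw_probabilities, student_t_statistics


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(tuple(f"g{i:03d}" for i in range(values.shape[0])),
                            tuple(f"s{j}" for j in range(values.shape[1])), values)


class TestSelectFeatures:
    def test_hand_computed_t_statistic(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se sqrt(2/3), t = -3/sqrt(2/3)
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        t = student_t_statistics(m, [1, 1, 1, 0, 0, 0])
        assert t[0] == pytest.approx(-3.674, abs=5e-4)

    def test_k_equal_to_all_features_returns_sorted(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(8, 1, size=(12, 10)))
        y = [1] * 5 + [0] * 5
        sel = select_features(m, y, 12)
        assert set(sel.feature_ids) == set(m.feature_ids)
        assert np.all(np.diff(np.abs(sel.t_statistics)) <= 1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, size=(20, 12)))
        y = np.array([1] * 7 + [0] * 5)
        perm = rng.permutation(12)
        permuted = ExpressionMatrix(m.feature_ids,
                                    tuple(m.sample_ids[i] for i in perm),
                                    m.values[:, perm])
        s1 = select_features(m, y, 5)
        s2 = select_features(permuted, y[perm], 5)
        assert s1.feature_ids == s2.feature_ids
        np.testing.assert_allclose(s1.t_statistics, s2.t_statistics)

    def test_equivariant_to_feature_permutation(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(8, 1, size=(20, 12)))
        y = [1] * 7 + [0] * 5
        perm = rng.permutation(20)
        permuted = ExpressionMatrix(tuple(m.feature_ids[i] for i in perm),
                                    m.sample_ids, m.values[perm])
        assert select_features(m, y, 6).feature_ids == \
               select_features(permuted, y, 6).feature_ids

    def test_small_class_rejected(self):
        m = _matrix(np.ones((3, 4)) + np.arange(4))
        with pytest.raises(ValueError, match=">= 2 samples"):
            student_t_statistics(m, [1, 0, 0, 0])

    def test_zero_variance_gene_handled_by_sd_floor(self):
        m = _matrix([[1.0, 1.0, 2.0, 2.0], [3.0, 4.0, 5.0, 6.0]])
        t = student_t_statistics(m, [1, 1, 0, 0])
        assert np.isfinite(t).all()
        assert abs(t[0]) > 1e6   # floored sd makes the degenerate gene dominate


class TestFactorize:
    def test_rank_two_matrix_reconstructed_exactly(self):
        rng = np.random.default_rng(5)
        a = np.outer(rng.normal(size=10), rng.normal(size=6))
        b = np.outer(rng.normal(size=10), rng.normal(size=6))
        m = _matrix(8.0 + a + b)
        fac = factorize(m)
        recon = fac.gene_centers[:, None] + fac.loadings @ fac.factor_scores.T
        np.testing.assert_allclose(recon, m.values, atol=1e-10)

    def test_training_columns_project_to_stored_scores(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(8, 2, size=(30, 10)))
        fac = factorize(m)
        for j in range(10):
            np.testing.assert_allclose(project(fac, m.values[:, j]),
                                       fac.factor_scores[j], atol=1e-8)

    def test_singular_values_match_eigendecomposition(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(8, 2, size=(30, 10)))
        fac = factorize(m)
        centered = m.values - m.values.mean(axis=1, keepdims=True)
        eigvals = np.linalg.eigvalsh(centered @ centered.T)[::-1]
        np.testing.assert_allclose(fac.singular_values**2, eigvals[:2], rtol=1e-10)

    def test_projection_of_centers_is_origin(self):
        rng = np.random.default_rng(8)
        fac = factorize(_matrix(rng.normal(8, 2, size=(20, 8))))
        np.testing.assert_allclose(project(fac, fac.gene_centers), [0.0, 0.0],
                                   atol=1e-12)

    def test_projection_ignores_null_space_directions(self):
        rng = np.random.default_rng(9)
        fac = factorize(_matrix(rng.normal(8, 2, size=(20, 8))))
        v = rng.normal(size=20)
        v -= fac.loadings @ (fac.loadings.T @ v)   # remove loading components
        x = rng.normal(8, 2, size=20)
        np.testing.assert_allclose(project(fac, x), project(fac, x + 3.0 * v),
                                   atol=1e-8)

    def test_rank_deficient_matrix_rejected(self):
        m = _matrix(np.outer(np.arange(1.0, 6.0), np.ones(4)) + 1.0)
        with pytest.raises(ValueError, match="rank"):
            factorize(m)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        fac = factorize(_matrix(rng.normal(8, 2, size=(20, 8))))
        with pytest.raises(ValueError, match="length"):
            project(fac, np.zeros(19))


class TestFitBpr:
    def test_chain_reproducible_given_seed(self):
        rng = np.random.default_rng(20)
        f = rng.standard_normal((30, 2))
        y = (rng.random(30) < ndtr(f[:, 0])).astype(int)
        cfg = McmcConfig(800, 200)
        p1 = fit_bpr(f, y, seed=5, config=cfg)
        p2 = fit_bpr(f, y, seed=5, config=cfg)
        np.testing.assert_array_equal(p1.draws, p2.draws)
        assert np.any(fit_bpr(f, y, seed=6, config=cfg).draws != p1.draws)

    def test_no_signal_probabilities_match_prevalence(self, fast_mcmc):
        rng = np.random.default_rng(21)
        f = rng.standard_normal((120, 2))
        y = np.array([1] * 80 + [0] * 40)     # labels independent of factors
        post = fit_bpr(f, y, seed=3, config=fast_mcmc)
        mean_p = _draw_probabilities(post.draws, f).mean()
        assert abs(mean_p - 80 / 120) < 0.1

    def test_large_separation_saturates_probabilities(self, fast_mcmc):
        rng = np.random.default_rng(22)
        n = 30
        y = np.array([1] * 15 + [0] * 15)
        f = np.column_stack([np.where(y == 1, 3.0, -3.0)
                             + 0.5 * rng.standard_normal(n),
                             rng.standard_normal(n)])   # ~6 sd separation
        post = fit_bpr(f, y, seed=4, config=fast_mcmc)
        p = _draw_probabilities(post.draws, f).mean(axis=1)
        assert np.all(np.abs(p - y) < 0.05)

    def test_label_flip_negates_posterior_mean(self):
        rng = np.random.default_rng(23)
        f = rng.standard_normal((150, 2))
        y = (rng.random(150) < ndtr(0.8 * f[:, 0])).astype(int)
        cfg = McmcConfig(4000, 1000)
        m1 = fit_bpr(f, y, seed=7, config=cfg).mean
        m2 = fit_bpr(f, 1 - y, seed=8, config=cfg).mean
        np.testing.assert_allclose(m1, -m2, atol=0.15)

    def test_summary_consistent_with_draws(self, fast_mcmc):
        rng = np.random.default_rng(24)
        f = rng.standard_normal((40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        if 0 not in y or 1 not in y:
            y[:2] = [0, 1]
        post = fit_bpr(f, y, seed=9, config=fast_mcmc)
        np.testing.assert_allclose(post.summary["mean"], post.draws.mean(axis=0))
        lo, hi = np.percentile(post.draws, [2.5, 97.5], axis=0)
        np.testing.assert_allclose(post.summary["ci_lo"], lo)
        np.testing.assert_allclose(post.summary["ci_hi"], hi)

    def test_degenerate_inputs_rejected(self, fast_mcmc):
        with pytest.raises(ValueError):
            fit_bpr(np.zeros((3, 2)), [1, 0, 1], seed=1, config=fast_mcmc)
        with pytest.raises(ValueError):
            fit_bpr(np.zeros((5, 2)), [1, 1, 1, 1, 1], seed=1, config=fast_mcmc)


class TestPrediction:
    def test_all_zero_draws_give_exactly_half(self, signal_cohort):
        matrix, _, labels, _ = signal_cohort
        results = SignatureModel(matrix, labels, 20, McmcConfig(600, 100)).fit(1)
        record = results.to_record()
        record.posterior_draws = np.zeros_like(record.posterior_draws)
        from bprsig import predict_record

        preds = predict_record(record, matrix)
        assert (preds["probability"] == 0.5).all()

    def test_probability_monotone_in_first_factor(self, signal_cohort):
        matrix, _, labels, _ = signal_cohort
        results = SignatureModel(matrix, labels, 20, McmcConfig(600, 100)).fit(1)
        draws = np.abs(results.posterior.draws)    # force all beta1 > 0
        probs = [float(_draw_probabilities(draws, np.array([[f1, 0.0]])).mean())
                 for f1 in np.linspace(-2, 2, 5)]
        assert np.all(np.diff(probs) >= 0)

    def test_missing_features_error_lists_them(self, signal_cohort):
        matrix, _, labels, _ = signal_cohort
        results = SignatureModel(matrix, labels, 20, McmcConfig(600, 100)).fit(1)
        stripped = matrix.select_features(
            [f for f in matrix.feature_ids
             if f not in set(results.selection.feature_ids[:3])])
        with pytest.raises(KeyError, match=results.selection.feature_ids[0]):
            results.predict(stripped)

    def test_credible_interval_brackets_probability(self, signal_cohort):
        matrix, _, labels, _ = signal_cohort
        results = SignatureModel(matrix, labels, 20, McmcConfig(600, 100)).fit(1)
        preds = results.predict(matrix)
        assert (preds["ci_lo"] <= preds["probability"]).all()
        assert (preds["probability"] <= preds["ci_hi"]).all()

    def test_summary_prints_coefficients(self, signal_cohort):
        matrix, _, labels, _ = signal_cohort
        results = SignatureModel(matrix, labels, 20, McmcConfig(600, 100)).fit(1)
        text = results.summary()
        assert "factor1" in text and "intercept" in text
        assert f"{results.model.k}" in text
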