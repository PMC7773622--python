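"""PCA reduction, the two logistic models, AUC and cross-validation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm

import _oracles
from trabpipe.classify import (
    BayesLogit,
    ElasticNetLogit,
    grid_search_en,
    make_blr_fitter,
    make_en_fitter,
    pca_reduce,
    repeated_kfold,
    roc_auc,
)


def _logistic_data(rng, n=200, beta=(0.8, -0.5, 0.3), intercept=0.2):
    X = rng.standard_normal((n, len(beta)))
    eta = intercept + X @ np.array(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestPCA:
    def test_full_threshold_retains_all_nonzero_components(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)))
        basis, scores = pca_reduce(X, var_threshold=1.0)
        assert basis.n_retained == 4
        assert scores.shape == (50, 4)

    def test_duplicated_column_gives_zero_eigenvalue(self, rng):
        X = rng.standard_normal((60, 3))
        Xd = np.column_stack([X, X[:, 0]])
        basis, _ = pca_reduce(pd.DataFrame(Xd), var_threshold=1.0)
        assert basis.explained_variance_ratio[-1] == pytest.approx(0.0, abs=1e-10)

    def test_two_feature_closed_form_eigenvalues(self, rng):
        # standardized 2-feature data with correlation r has eigenvalues 1 +/- r
        r = 0.9
        cov = np.array([[1, r], [r, 1]])
        X = rng.multivariate_normal([0, 0], cov, size=20000)
        basis, _ = pca_reduce(pd.DataFrame(X), var_threshold=1.0)
        assert basis.explained_variance_ratio[0] == pytest.approx((1 + r) / 2, abs=0.01)

    def test_retention_is_smallest_prefix(self, rng):
        X = rng.standard_normal((200, 6)) @ np.diag([5, 3, 1, 0.5, 0.3, 0.1])
        basis, _ = pca_reduce(pd.DataFrame(X), var_threshold=0.98)
        cum = np.cumsum(basis.explained_variance_ratio)
        assert cum[basis.n_retained - 1] >= 0.98
        assert basis.n_retained == 1 or cum[basis.n_retained - 2] < 0.98

    def test_reconstruction_from_all_components(self, rng):
        X = rng.standard_normal((30, 5))
        basis, _ = pca_reduce(pd.DataFrame(X), var_threshold=1.0)
        Z = (X - basis.means) / basis.sds
        np.testing.assert_allclose(Z @ basis.loadings @ basis.loadings.T, Z, atol=1e-10)

    def test_constant_column_instructive_error(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "b": np.ones(20)})
        with pytest.raises(ValueError, match="constant column"):
            pca_reduce(X)


class TestBayesLogit:
    def test_flat_prior_matches_mle(self, rng):
        X, y = _logistic_data(rng)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        res = BayesLogit(y, X, prior_scale=1e6, intercept_scale=1e6).fit()
        np.testing.assert_allclose(res.params, mle, atol=1e-4)

    def test_complete_separation_stays_finite(self):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(float)
        res = BayesLogit(y, X).fit()
        assert np.all(np.isfinite(res.params))
        # prior-regularized slope exceeds any null-data slope but is bounded
        assert 1.0 < res.params[1] < 1e3

    def test_null_data_slopes_near_zero(self):
        # labels independent of features: slopes concentrate near zero
        gen = np.random.default_rng(0)
        X = gen.standard_normal((500, 4))
        y = gen.integers(0, 2, 500).astype(float)
        res = BayesLogit(y, X).fit()
        assert np.all(np.abs(res.params[1:]) < 0.2)

    def test_predictions_and_summary(self, rng):
        X, y = _logistic_data(rng)
        res = BayesLogit(y, X).fit()
        p = res.predict(X)
        assert p.shape == (len(y),) and (0 < p).all() and (p < 1).all()
        text = res.summary()
        assert "coef (MAP)" in text and "t prior" in text

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="both classes"):
            BayesLogit(np.ones(10), X)


class TestElasticNet:
    def test_unpenalized_matches_mle(self, rng):
        X, y = _logistic_data(rng)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        res = ElasticNetLogit(y, X, alpha=0.5, lam=0.0).fit()
        np.testing.assert_allclose(res.params, mle, atol=1e-4)

    def test_huge_lasso_penalty_zeroes_slopes(self, rng):
        X, y = _logistic_data(rng)
        res = ElasticNetLogit(y, X, alpha=1.0, lam=10.0).fit()
        assert np.all(res.params[1:] == 0.0)
        assert res.params[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_matches_saga_solver(self, rng):
        X, y = _logistic_data(rng)
        Xs = (X - X.mean(0)) / X.std(0)
        alpha, lam = 0.6, 0.02
        from sklearn.linear_model import LogisticRegression

        sk = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=1.0 / (len(y) * lam), max_iter=100000, tol=1e-10
        ).fit(Xs, y)
        res = ElasticNetLogit(y, Xs, alpha=alpha, lam=lam).fit()
        np.testing.assert_allclose(
            res.params, np.concatenate([sk.intercept_, sk.coef_[0]]), atol=1e-5
        )

    def test_ridge_splits_lasso_concentrates_on_duplicates(self, rng):
        X, y = _logistic_data(rng, n=300, beta=(1.0,))
        Xd = np.column_stack([X[:, 0], X[:, 0]])
        ridge = ElasticNetLogit(y, Xd, alpha=0.0, lam=0.05).fit()
        lasso = ElasticNetLogit(y, Xd, alpha=1.0, lam=0.05).fit()
        assert ridge.params[1] == pytest.approx(ridge.params[2], rel=1e-3)
        assert min(abs(lasso.params[1:])) < 1e-8 < max(abs(lasso.params[1:]))

    def test_regularization_path_monotonicity(self, rng):
        X, y = _logistic_data(rng)
        l1_norms = []
        for lam in (0.001, 0.01, 0.05, 0.1, 0.3):
            res = ElasticNetLogit(y, X, alpha=1.0, lam=lam).fit()
            l1_norms.append(np.abs(res.params[1:]).sum())
        assert all(a >= b - 1e-8 for a, b in zip(l1_norms, l1_norms[1:]))

    def test_invalid_hyperparameters_rejected(self, rng):
        X, y = _logistic_data(rng, n=40)
        with pytest.raises(ValueError):
            ElasticNetLogit(y, X, alpha=1.5, lam=0.1)
        with pytest.raises(ValueError):
            ElasticNetLogit(y, X, alpha=0.5, lam=-0.1)


class TestAUC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc(np.ones(10), [0, 1] * 5)
        assert auc == 0.5

    def test_six_point_toy_with_tie(self):
        scores = [0.1, 0.4, 0.4, 0.6, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(_oracles.auc_pairwise(scores, labels))

    def test_matches_pairwise_concordance_with_ties(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, 30).astype(float)  # many ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            auc, curve = roc_auc(scores, labels)
            assert auc == pytest.approx(_oracles.auc_pairwise(scores, labels))
            # trapezoidal area under the swept curve equals the U-statistic
            assert np.trapezoid(curve["tpr"], curve["fpr"]) == pytest.approx(auc)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRepeatedKFold:
    def test_deterministic_scorer_zero_ci_width(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.array([0, 1] * 20)

        def fitter(Xtr, ytr):
            return lambda Xte: Xte[:, 0]

        cv = repeated_kfold(X, y, fitter, k=10, repeats=5, seed=0)
        assert np.ptp(cv.repeat_aucs) == 0.0
        assert cv.ci_low == cv.ci_high == cv.mean_auc

    def test_every_subject_held_out_once_per_repeat(self, rng):
        X = rng.standard_normal((40, 2))
        y = np.array([0, 1] * 20)
        seen = []

        def fitter(Xtr, ytr):
            assert len(Xtr) == 36  # k=10 on n=40 holds out 4 per fold
            assert set(ytr) == {0, 1}
            seen.append(len(Xtr))
            return lambda Xte: Xte[:, 0]

        cv = repeated_kfold(X, y, fitter, k=10, repeats=2, seed=1)
        assert len(seen) == 20  # 10 folds x 2 repeats
        assert cv.scores.shape == (2, 40)

    def test_reproducible_from_seed(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.array([0, 1] * 30)
        f = make_en_fitter(0.5, 0.01)
        cv1 = repeated_kfold(X, y, f, k=5, repeats=3, seed=42)
        cv2 = repeated_kfold(X, y, f, k=5, repeats=3, seed=42)
        np.testing.assert_array_equal(cv1.repeat_aucs, cv2.repeat_aucs)

    def test_binormal_single_feature_auc(self):
        # one Gaussian feature at separation d=1: population AUC = Phi(d/sqrt 2)
        rng = np.random.default_rng(5)
        n = 300
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])[:, None]
        y = np.r_[np.zeros(n), np.ones(n)].astype(int)
        cv = repeated_kfold(X, y, make_blr_fitter(), k=10, repeats=5, seed=0)
        assert cv.mean_auc == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.04)

    def test_too_small_n_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            repeated_kfold(X, y, make_en_fitter(0.5, 0.01), k=10, repeats=1, seed=0)


class TestGridSearchEN:
    def test_single_point_grid_returned(self, rng):
        X, y = _logistic_data(rng, n=60, beta=(1.0, 0.0))
        alpha, lam, cv = grid_search_en(X, y, alphas=[0.4], lambdas=[0.02], k=5, repeats=2, seed=0)
        assert (alpha, lam) == (0.4, 0.02)
        assert cv.chosen_params == {"alpha": 0.4, "lambda": 0.02}

    def test_pure_noise_near_chance(self):
        # average over independent null draws; a single small cohort can sit
        # far from 0.5 by chance
        aucs = []
        for s in range(3):
            gen = np.random.default_rng(s)
            X = gen.standard_normal((200, 5))
            y = gen.integers(0, 2, 200)
            _, _, cv = grid_search_en(
                X, y, alphas=[0.5], lambdas=[0.01, 0.1], k=5, repeats=2, seed=s
            )
            aucs.append(cv.mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_planted_signal_feature_retained(self, rng):
        n = 120
        X = rng.standard_normal((n, 4))
        eta = 2.5 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        alpha, lam, _ = grid_search_en(
            X, y, alphas=[0.5, 1.0], lambdas=[0.005, 0.05], k=5, repeats=2, seed=0
        )
        res = ElasticNetLogit(y, X, alpha, lam).fit()
        assert res.params[3] != 0.0

    def test_empty_grid_rejected(self, rng):
        X, y = _logistic_data(rng, n=40)
        with pytest.raises(ValueError, match="empty"):
            grid_search_en(X, y, alphas=[], lambdas=[0.1])
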