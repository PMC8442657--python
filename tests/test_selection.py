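"""Selectors: screening ranking, penalized-GLM engine vs scikit-learn and
KKT oracles, contract properties (cap, determinism, 1-based indices)."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet, LogisticRegression

from ssglm.selection import (default_size_cap, elastic_net_select,
                             get_selector, lasso_select, mcp_select,
                             scad_select, sis_screen, _standardize)
from ssglm import _coordinate_descent as cd


class TestSIS:
    def test_exact_copy_ranked_first(self, rng):
        X = rng.standard_normal((60, 12))
        y = X[:, 6].copy()  # predictor 7 (1-based)
        res = sis_screen(X, y, "gaussian", d=3)
        assert 7 in res.selected

    def test_d_equals_p_keeps_everything(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        res = sis_screen(X, y, "gaussian", d=8)
        np.testing.assert_array_equal(res.selected, np.arange(1, 9))

    def test_deterministic(self, rng):
        X = rng.standard_normal((50, 30))
        y = rng.standard_normal(50)
        a = sis_screen(X, y, "gaussian", d=5)
        b = sis_screen(X, y, "gaussian", d=5)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_size_cap_and_errors(self, rng):
        X = rng.standard_normal((30, 50))
        y = rng.standard_normal(30)
        res = sis_screen(X, y, "gaussian", d=25)
        assert res.selected.size <= default_size_cap(30)
        with pytest.raises(ValueError, match="must be <"):
            sis_screen(X, y, "gaussian", d=30)
        with pytest.raises(ValueError, match=">= 1"):
            sis_screen(X, y, "gaussian", d=0)

    def test_rank_utility_matches_score_for_binary(self, rng):
        # for a 0/1 response the rank transform is affine in y
        X = rng.standard_normal((80, 20))
        y = (rng.random(80) < 0.4).astype(float)
        a = sis_screen(X, y, "binomial", d=6, utility="rank")
        b = sis_screen(X, y, "binomial", d=6, utility="score")
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_rank_utility_detects_weak_poisson_signal(self, rng):
        # a raw-scale screen is diluted by the response's huge variance
        hits = 0
        for _ in range(20):
            X = rng.standard_normal((150, 60))
            eta = 1.0 + 0.6 * X[:, 4] + 1.2 * X[:, 30]
            y = rng.poisson(np.exp(np.clip(eta, -20, 8))).astype(float)
            res = sis_screen(X, y, "poisson", d=8)
            hits += {5, 31} <= set(res.selected.tolist())
        assert hits >= 17


class TestPenalizedEngine:
    """Dual-route checks of the coordinate-descent solver."""

    def test_gaussian_path_matches_sklearn_elastic_net(self, rng):
        n, p = 100, 30
        X = rng.standard_normal((n, p))
        y = X[:, 3] - 0.8 * X[:, 11] + rng.standard_normal(n)
        Xs, _ = _standardize(X)
        for lam in (0.3, 0.1, 0.02):
            b0s, betas = cd.enet_path_fit(Xs, y, "gaussian", alpha=1.0,
                                          lams=np.array([lam]),
                                          tol_cd=1e-13)
            ref = ElasticNet(alpha=lam, l1_ratio=1.0, fit_intercept=True,
                             tol=1e-10, max_iter=50000).fit(Xs, y)
            np.testing.assert_allclose(betas[0], ref.coef_, atol=2e-5)
            assert b0s[0] == pytest.approx(ref.intercept_, abs=2e-5)

    def test_logistic_lasso_matches_sklearn(self, rng):
        n, p = 150, 12
        X = rng.standard_normal((n, p))
        eta = 1.2 * X[:, 0] - 1.0 * X[:, 5]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        Xs, _ = _standardize(X)
        lam = 0.05
        _, betas = cd.enet_path_fit(Xs, y, "binomial", alpha=1.0,
                                    lams=np.array([lam]), tol_cd=1e-13,
                                    tol_outer=1e-9)
        # saga leaves the intercept unpenalized, matching this solver
        ref = LogisticRegression(penalty="l1", C=1.0 / (n * lam),
                                 solver="saga", tol=1e-8,
                                 max_iter=50000).fit(Xs, y)
        np.testing.assert_allclose(betas[0], ref.coef_[0], atol=5e-4)

    def test_poisson_lasso_satisfies_kkt(self, rng):
        # no reference solver exists for L1 Poisson; verify the stationarity
        # conditions directly:  |x_j'(y-mu)/n| <= lam on the zero set and
        # x_j'(y-mu)/n = lam*sign(b_j) on the active set
        n, p = 200, 40
        X = rng.standard_normal((n, p))
        eta = 0.5 + 0.7 * X[:, 2] - 0.5 * X[:, 17]
        y = rng.poisson(np.exp(eta)).astype(float)
        Xs, _ = _standardize(X)
        lam = 0.05
        b0s, betas = cd.enet_path_fit(Xs, y, "poisson", alpha=1.0,
                                      lams=np.array([lam]))
        mu = np.exp(b0s[0] + Xs @ betas[0])
        grad = Xs.T @ (mu - y) / n
        zero = betas[0] == 0
        assert np.all(np.abs(grad[zero]) <= lam + 1e-4)
        active = ~zero
        np.testing.assert_allclose(grad[active],
                                   -lam * np.sign(betas[0][active]),
                                   atol=1e-4)
        assert abs(np.mean(mu - y)) < 1e-6  # unpenalized intercept score

    def test_poisson_lasso_matches_glm_when_unpenalized(self, rng):
        from ssglm.glm import fit_glm
        n, p = 150, 4
        X = rng.standard_normal((n, p))
        y = rng.poisson(np.exp(0.3 + 0.5 * X[:, 0])).astype(float)
        Xs, _ = _standardize(X)
        b0s, betas = cd.enet_path_fit(Xs, y, "poisson", alpha=1.0,
                                      lams=np.array([1e-8]))
        ref = fit_glm("poisson", Xs, y)
        np.testing.assert_allclose(np.r_[b0s[0], betas[0]], ref.coefficients,
                                   atol=1e-4)


class TestSelectors:
    def test_strong_signal_recovered_by_lasso(self, rng):
        # Monte-Carlo contract: a dominant signal must be found essentially
        # always; signal strength confirmed by the closed-form OLS oracle
        hits = 0
        reps = 40
        for r in range(reps):
            X = rng.standard_normal((150, 50))
            y = 5.0 * X[:, 20] + rng.standard_normal(150)
            ols = np.linalg.lstsq(np.column_stack([np.ones(150), X]), y,
                                  rcond=None)[0]
            assert abs(ols[21]) > 4  # the signal really is dominant
            res = lasso_select(X, y, "gaussian", rng=np.random.default_rng(r))
            hits += 21 in res.selected
        assert hits >= int(0.95 * reps)

    def test_all_selectors_find_orthogonal_signal(self, rng):
        X = rng.standard_normal((120, 30))
        y = 4.0 * X[:, 9] + rng.standard_normal(120)
        for select in (lasso_select, elastic_net_select, scad_select,
                       mcp_select):
            res = select(X, y, "gaussian", rng=np.random.default_rng(0))
            assert 10 in res.selected, select.__name__
        res = sis_screen(X, y, "gaussian", d=5)
        assert 10 in res.selected

    def test_elastic_net_mixing_one_reduces_to_lasso(self, rng):
        X = rng.standard_normal((100, 40))
        y = 2.0 * X[:, 5] - X[:, 25] + rng.standard_normal(100)
        a = lasso_select(X, y, "gaussian", rng=np.random.default_rng(3))
        b = elastic_net_select(X, y, "gaussian", mixing=1.0,
                               rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_all_noise_respects_cap(self, rng):
        X = rng.standard_normal((90, 60))
        y = rng.standard_normal(90)
        res = lasso_select(X, y, "gaussian", rng=np.random.default_rng(1))
        assert 1 <= res.selected.size <= default_size_cap(90)
        assert res.selected.min() >= 1 and res.selected.max() <= 60

    def test_empty_support_falls_back_to_one_predictor(self, rng, caplog):
        # a nearly flat path (lambda_min ~ lambda_max) keeps the support
        # empty at the chosen lambda
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        res = lasso_select(X, y, "gaussian", rng=np.random.default_rng(0),
                           n_lambda=2, lambda_min_ratio=0.999)
        assert res.selected.size == 1

    def test_registry(self):
        assert get_selector("sis") is sis_screen
        with pytest.raises(ValueError, match="unknown selector"):
            get_selector("bayes")
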