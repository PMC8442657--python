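"""Variance estimators against brute-force double-sum oracles; CI/p-value
formulas against independent normal evaluations; Wald identities."""

import numpy as np
import pytest
from scipy import stats

from ssglm.estimator import SSGLMConfig, SSGLMFit, SplitRecord, SubvectorFit
from ssglm.inference import (bias_corrected_variance, ij_variance,
                             inference_table, subvector_covariance,
                             wald_contrast_test)


def brute_force_V(J, bt, n1):
    """Nested-loop evaluation of the infinitesimal-jackknife variance."""
    B, n = J.shape
    bhat = sum(bt) / B
    Jbar = [sum(J[b, i] for b in range(B)) / B for i in range(n)]
    total = 0.0
    for i in range(n):
        cov = sum((J[b, i] - Jbar[i]) * (bt[b] - bhat)
                  for b in range(B)) / B
        total += cov**2
    return n * (n - 1) / (n - n1) ** 2 * total


def brute_force_correction(bt, n, n1):
    B = len(bt)
    bhat = sum(bt) / B
    return (n / B**2) * (n1 / (n - n1)) * sum((b - bhat) ** 2 for b in bt)


@pytest.fixture
def fixture_splits():
    # hand-chosen B=3, n=5 fixture with n1=2
    J = np.array([[1, 1, 0, 0, 0],
                  [0, 1, 1, 0, 0],
                  [1, 0, 0, 0, 1]], dtype=float)
    bt = np.array([[0.7, -0.2],
                   [1.1, 0.15],
                   [0.4, -0.05]])
    return J, bt, 2, 5


class TestIJVariance:
    def test_matches_brute_force_double_sum(self, fixture_splits):
        J, bt, n1, n = fixture_splits
        V = ij_variance(J, bt, n1)
        for j in range(bt.shape[1]):
            assert V[j] == pytest.approx(brute_force_V(J, bt[:, j], n1),
                                         abs=1e-12)

    def test_bias_correction_matches_direct_formula(self, fixture_splits):
        J, bt, n1, n = fixture_splits
        V = ij_variance(J, bt, n1)
        VB = bias_corrected_variance(V, J, bt, n1)
        for j in range(bt.shape[1]):
            expected = V[j] - brute_force_correction(bt[:, j], n, n1)
            if expected >= 0:
                assert VB[j] == pytest.approx(expected, abs=1e-12)
            else:
                assert VB[j] == pytest.approx(V[j])  # conservative fallback

    def test_constant_estimates_give_zero_variance(self):
        J = np.array([[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]], float)
        bt = np.full((3, 1), 2.5)
        V = ij_variance(J, bt, 2)
        VB = bias_corrected_variance(V, J, bt, 2)
        assert V[0] == 0.0 and VB[0] == 0.0

    def test_correction_never_exceeds_raw(self, rng):
        for _ in range(20):
            B, n, n1 = 12, 9, 4
            J = np.zeros((B, n))
            for b in range(B):
                J[b, rng.choice(n, n1, replace=False)] = 1
            bt = rng.standard_normal((B, 3))
            V = ij_variance(J, bt, n1)
            VB = bias_corrected_variance(V, J, bt, n1)
            assert np.all(VB <= V + 1e-15)
            assert np.all(V >= 0)

    def test_missing_splits_use_their_own_count(self, fixture_splits):
        J, bt, n1, n = fixture_splits
        btm = bt.copy()
        btm[1, 0] = np.nan  # column 0 usable in splits {0, 2} only
        V = ij_variance(J, btm, n1)
        expected = brute_force_V(J[[0, 2]], bt[[0, 2], 0], n1)
        assert V[0] == pytest.approx(expected, abs=1e-12)
        assert V[1] == pytest.approx(brute_force_V(J, bt[:, 1], n1), abs=1e-12)

    def test_fewer_than_two_splits_is_an_error(self, fixture_splits):
        J, bt, n1, n = fixture_splits
        btm = bt.copy()
        btm[1:, 0] = np.nan
        with pytest.raises(ValueError, match="variance undefined"):
            ij_variance(J, btm, n1)


def _make_fit(J, bt, q=0.4, selected=None):
    B, n = J.shape
    p = bt.shape[1] - 1
    cfg = SSGLMConfig(B=B, q=q, seed=0)
    from ssglm.selection import SelectionResult
    sel = SelectionResult(np.array(selected if selected is not None else [1]),
                          "sis")
    splits = [SplitRecord(b=b, J=J[b].astype(bool), selection=sel,
                          beta_tilde=bt[b], converged=~np.isnan(bt[b]))
              for b in range(B)]
    return SSGLMFit(beta_hat=np.nanmean(bt, axis=0), splits=splits,
                    config=cfg, n=n, p=p)


class TestInferenceTable:
    @pytest.fixture
    def fit(self, rng):
        B, n, n1 = 20, 10, 4
        J = np.zeros((B, n))
        for b in range(B):
            J[b, rng.choice(n, n1, replace=False)] = 1
        bt = rng.standard_normal((B, 4)) * 0.3 + [0.0, 1.0, -0.5, 0.2]
        return _make_fit(J, bt, q=0.4)

    def test_ci_and_pvalue_formulas(self, fit):
        tab = inference_table(fit, alpha=0.05)
        z = stats.norm.ppf(0.975)
        np.testing.assert_allclose(
            tab["ci_hi"] - tab["estimate"], z * tab["se"], rtol=1e-12)
        np.testing.assert_allclose(
            tab["ci_lo"] - tab["estimate"], -z * tab["se"], rtol=1e-12)
        expected_p = 2 * (1 - stats.norm.cdf(
            np.abs(tab["estimate"]) / tab["se"]))
        np.testing.assert_allclose(tab["pvalue"], expected_p, atol=1e-12)

    def test_zero_estimate_has_pvalue_one(self, fit):
        fit.beta_hat[2] = 0.0
        tab = inference_table(fit)
        assert tab.loc[2, "pvalue"] == pytest.approx(1.0)

    def test_quantile_boundary_case(self):
        # estimate / SE at the 97.5% normal quantile => p ~ alpha
        p = 2 * (1 - stats.norm.cdf(1.959964))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_bonferroni_adjustment(self, fit):
        tab = inference_table(fit, adjust="bonferroni")
        np.testing.assert_allclose(
            tab["pvalue_adj"][1:], np.minimum(tab["pvalue"][1:] * fit.p, 1.0))
        assert np.isnan(tab.loc[0, "pvalue_adj"])
        with pytest.raises(ValueError, match="unknown adjustment"):
            inference_table(fit, adjust="holm")

    def test_invalid_alpha(self, fit):
        with pytest.raises(ValueError, match="alpha"):
            inference_table(fit, alpha=1.5)


def _make_subfit(J, bt, q, S1):
    B, n = J.shape
    return SubvectorFit(S1=np.asarray(S1), beta1_hat=np.nanmean(bt, axis=0),
                        beta_tilde=bt, J_matrix=J.astype(bool),
                        splits_meta=[None] * B,
                        config=SSGLMConfig(B=B, q=q, seed=0), n=n)


class TestSubvectorCovariance:
    def test_diagonal_matches_scalar_variances(self, rng):
        B, n, n1 = 200, 12, 6
        J = np.zeros((B, n))
        for b in range(B):
            J[b, rng.choice(n, n1, replace=False)] = 1
        # estimates genuinely driven by split membership, so the jackknife
        # covariance dominates the Monte-Carlo correction
        M = rng.standard_normal((n, 3))
        bt = (J - n1 / n) @ M + 0.01 * rng.standard_normal((B, 3))
        sub = _make_subfit(J, bt, 0.5, [4, 9, 11])
        V = ij_variance(J, bt, n1)
        Sigma_raw = subvector_covariance(sub, bias_correct=False)
        np.testing.assert_allclose(np.diag(Sigma_raw), V, atol=1e-12)
        VB = bias_corrected_variance(V, J, bt, n1)
        Sigma = subvector_covariance(sub, bias_correct=True)
        assert np.all(VB < V)  # correction active, no fallback in this regime
        np.testing.assert_allclose(np.diag(Sigma), VB, atol=1e-10)

    def test_constant_estimates_give_zero_matrix(self):
        J = np.array([[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]], float)
        bt = np.tile([1.0, -2.0], (3, 1))
        sub = _make_subfit(J, bt, 0.5, [1, 2])
        np.testing.assert_allclose(
            subvector_covariance(sub, bias_correct=False), 0.0, atol=1e-15)

    def test_symmetric_psd(self, rng):
        B, n, n1 = 25, 10, 5
        J = np.zeros((B, n))
        for b in range(B):
            J[b, rng.choice(n, n1, replace=False)] = 1
        bt = rng.standard_normal((B, 2))
        sub = _make_subfit(J, bt, 0.5, [1, 2])
        S = subvector_covariance(sub)
        np.testing.assert_allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() >= -1e-12


class TestWaldContrast:
    def setup_method(self):
        self.beta = np.array([1.0, -0.5, 2.0])
        self.Sigma = np.array([[0.20, 0.02, 0.0],
                               [0.02, 0.15, 0.01],
                               [0.0, 0.01, 0.30]])

    def test_null_contrast_gives_zero_statistic(self):
        Q = np.eye(3)
        res = wald_contrast_test(self.beta, self.Sigma, Q, self.beta)
        assert res.T == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_row_equals_squared_z(self):
        Q = np.array([[0.0, 1.0, 0.0]])
        res = wald_contrast_test(self.beta, self.Sigma, Q, [0.0])
        z = self.beta[1] / np.sqrt(self.Sigma[1, 1])
        assert res.T == pytest.approx(z**2, rel=1e-12)
        assert res.p_value == pytest.approx(
            2 * (1 - stats.norm.cdf(abs(z))), rel=1e-9)

    def test_row_scaling_invariance(self):
        Q = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, -1.0]])
        R = np.array([0.2, -1.0])
        a = wald_contrast_test(self.beta, self.Sigma, Q, R)
        D = np.diag([3.0, -0.5])
        b = wald_contrast_test(self.beta, self.Sigma, D @ Q, D @ R)
        assert a.T == pytest.approx(b.T, rel=1e-10)

    def test_rank_deficient_contrast_rejected(self):
        Q = np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="full row rank"):
            wald_contrast_test(self.beta, self.Sigma, Q, [0.0, 0.0])

    def test_singular_quadratic_form_rejected(self):
        Sigma = np.zeros((3, 3))
        Q = np.array([[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="singular"):
            wald_contrast_test(self.beta, Sigma, Q, [0.0])

    def test_chi2_reference(self):
        Q = np.eye(2, 3)
        res = wald_contrast_test(self.beta, self.Sigma, Q, [0.0, 0.0])
        assert res.p_value == pytest.approx(stats.chi2.sf(res.T, 2), rel=1e-12)
        assert res.df == 2
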