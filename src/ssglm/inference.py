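"""Inference for the smoothed estimator: infinitesimal-jackknife variances,
confidence intervals, p-values, subvector covariance and Wald contrast tests.

The variance of a smoothed coefficient is estimated from the covariance,
across the B splits, between the split-membership indicators J_bi and the
one-time estimates:

    cov_ij = (1/B) sum_b (J_bi - Jbar_i) (btilde_j^b - bhat_j)
    V_j    = n(n-1)/(n-n1)^2 * sum_i cov_ij^2

where n(n-1)/(n-n1)^2 is a finite-sample correction for subsampling without
replacement.  At finite B this overstates the truth by a Monte-Carlo term;
the bias-corrected version subtracts it:

    V_j^B  = V_j - (n/B^2) * (n1/(n-n1)) * sum_b (btilde_j^b - bhat_j)^2.

Confidence intervals and p-values use the normal reference with SE =
sqrt(V_j^B); contrasts Q beta^(1) = R use the chi-square Wald statistic with
the analogous subvector covariance estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import SSGLMFit, SubvectorFit

__all__ = ["ij_variance", "bias_corrected_variance", "variance_estimates",
           "inference_table", "subvector_covariance", "wald_contrast_test",
           "ContrastTest"]

logger = logging.getLogger(__name__)


def _columns(Btilde):
    """Yield (j, usable-row mask) for each coefficient column."""
    ok = ~np.isnan(Btilde)
    for j in range(Btilde.shape[1]):
        yield j, ok[:, j]


def _ij_correction(n: int, n1: int) -> float:
    return n * (n - 1) / (n - n1) ** 2


def ij_variance(J, Btilde, n1: int) -> np.ndarray:
    """Infinitesimal-jackknife variance V_j for each coefficient column.

    Parameters
    ----------
    J : (B, n) split-membership indicator matrix.
    Btilde : (B, P) per-split estimates; NaN rows of a column are dropped for
        that column (its own split count and mean are used).
    n1 : estimation-half size.

    Requires at least 2 usable splits per column.
    """
    J = np.asarray(J, dtype=float)
    Btilde = np.asarray(Btilde, dtype=float)
    B, n = J.shape
    c = _ij_correction(n, n1)
    V = np.empty(Btilde.shape[1])
    clean = ~np.any(np.isnan(Btilde), axis=0)
    if clean.any():
        Jc = J - J.mean(axis=0)
        D = Btilde[:, clean] - Btilde[:, clean].mean(axis=0)
        cov = Jc.T @ D / B
        V[clean] = c * np.sum(cov**2, axis=0)
    for j in np.flatnonzero(~clean):
        ok = ~np.isnan(Btilde[:, j])
        Bj = int(ok.sum())
        if Bj < 2:
            raise ValueError(
                f"variance undefined: coefficient {j} has {Bj} usable splits")
        Jj = J[ok]
        Jc = Jj - Jj.mean(axis=0)
        d = Btilde[ok, j] - Btilde[ok, j].mean()
        cov = Jc.T @ d / Bj
        V[j] = c * np.sum(cov**2)
    return V


def bias_corrected_variance(V, J, Btilde, n1: int) -> np.ndarray:
    """Monte-Carlo bias-corrected variance V_j^B.

    When the subtracted Monte-Carlo term overshoots (V_j^B < 0, which
    happens for individual coefficients when B is small relative to
    n*q/(1-q)), the correction is considered uninformative for that
    coefficient and the raw estimate V_j is used instead: the failure mode
    is then conservative (wider intervals), never a spuriously tiny
    variance.  Fallbacks are logged.
    """
    J = np.asarray(J, dtype=float)
    Btilde = np.asarray(Btilde, dtype=float)
    B, n = J.shape
    V = np.asarray(V, dtype=float)
    VB = np.empty_like(V)
    for j, ok in _columns(Btilde):
        col = Btilde[ok, j]
        Bj = col.size
        corr = (n / Bj**2) * (n1 / (n - n1)) * np.sum((col - col.mean())**2)
        VB[j] = V[j] - corr
    neg = VB < 0
    if np.any(neg):
        logger.info("bias correction overshot for %d coefficients; "
                    "falling back to the uncorrected variance there",
                    int(neg.sum()))
        VB[neg] = V[neg]
    return VB


@dataclass
class VarianceEstimate:
    V: np.ndarray        # raw IJ variance per coefficient
    VB: np.ndarray       # bias-corrected variance per coefficient
    B_used: np.ndarray   # usable split count per coefficient


def variance_estimates(fit: SSGLMFit) -> VarianceEstimate:
    J = fit.J_matrix
    Btilde = fit.beta_tilde_matrix
    V = ij_variance(J, Btilde, fit.n1)
    VB = bias_corrected_variance(V, J, Btilde, fit.n1)
    return VarianceEstimate(V=V, VB=VB, B_used=fit.n_used)


def inference_table(fit: SSGLMFit, alpha: float = 0.05,
                    adjust: str = "bonferroni") -> pd.DataFrame:
    """Per-coefficient estimates, SEs, level-(1-alpha) CIs and p-values.

    CI = bhat_j +- z_{1-alpha/2} * SE_j and p = 2(1 - Phi(|bhat_j|/SE_j))
    with SE_j = sqrt(V_j^B).  The Bonferroni adjustment multiplies the p
    non-intercept p-values by p (capped at 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ve = variance_estimates(fit)
    se = np.sqrt(ve.VB)
    z = stats.norm.ppf(1 - alpha / 2)
    est = fit.beta_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        pval = 2 * (1 - stats.norm.cdf(np.abs(est) / se))
    pval = np.where(se == 0, np.where(est == 0, 1.0, 0.0), pval)
    padj = np.minimum(pval * fit.p, 1.0)
    padj[0] = np.nan  # the intercept is outside the multiplicity family
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if adjust == "none":
        padj = np.full_like(pval, np.nan)
    names = ["(intercept)"] + [f"x{j}" for j in range(1, fit.p + 1)]
    return pd.DataFrame({
        "index": np.arange(fit.p + 1),
        "name": names,
        "estimate": est,
        "se": se,
        "ci_lo": est - z * se,
        "ci_hi": est + z * se,
        "pvalue": pval,
        "pvalue_adj": padj,
        "sel_freq": fit.selection_frequency,
    })


def subvector_covariance(sub: SubvectorFit, bias_correct: bool = True,
                         ) -> np.ndarray:
    """Covariance estimate Sigma^(1) of a smoothed subvector.

    Builds the n x p1 matrix of per-sample covariance rows
    C_i = (1/B) sum_b (J_bi - Jbar_i)(btilde^b - bhat) and returns the
    corrected Gram product ``n(n-1)/(n-n1)^2 * C'C`` — so the diagonal
    coincides with :func:`ij_variance` of each coordinate.  With
    ``bias_correct`` (default) the matrix analog of the scalar Monte-Carlo
    correction,
    ``(n/B^2)(n1/(n-n1)) sum_b (btilde^b - bhat)(btilde^b - bhat)'``,
    is subtracted (diagonals then coincide with the bias-corrected
    variances); any negative eigenvalues created by the subtraction are
    floored at zero (logged).
    """
    J = np.asarray(sub.J_matrix, dtype=float)
    Btilde = np.asarray(sub.beta_tilde, dtype=float)
    B, n = J.shape
    if B < 2:
        raise ValueError("variance undefined with fewer than 2 splits")
    n1 = sub.n1
    ok = ~np.any(np.isnan(Btilde), axis=1)
    if ok.sum() < 2:
        raise ValueError("variance undefined: fewer than 2 usable splits")
    J = J[ok]
    Btilde = Btilde[ok]
    Bu = int(ok.sum())
    Jc = J - J.mean(axis=0)
    D = Btilde - Btilde.mean(axis=0)
    C = Jc.T @ D / Bu
    Sigma = _ij_correction(n, n1) * (C.T @ C)
    if bias_correct:
        corr = (n / Bu**2) * (n1 / (n - n1)) * (D.T @ D)
        Sigma = Sigma - corr
        w, Q = np.linalg.eigh(Sigma)
        if np.any(w < 0):
            logger.info("flooring %d negative eigenvalues of Sigma^(1)",
                        int((w < 0).sum()))
            floor = 1e-10 * max(float(w.max()), 1e-30)
            Sigma = (Q * np.maximum(w, floor)) @ Q.T
    return Sigma


@dataclass
class ContrastTest:
    """Wald test of H0: Q beta^(1) = R."""

    S1: np.ndarray
    beta1_hat: np.ndarray
    Sigma1: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    T: float
    df: int
    p_value: float


def wald_contrast_test(beta1_hat, Sigma1, Q, R, S1=None) -> ContrastTest:
    """T = (Q bhat - R)' [Q Sigma Q']^{-1} (Q bhat - R) ~ chi2_r under H0.

    Q must have full row rank r <= p1 and Q Sigma Q' must be invertible.
    """
    beta1_hat = np.asarray(beta1_hat, dtype=float).ravel()
    Sigma1 = np.atleast_2d(np.asarray(Sigma1, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    R = np.atleast_1d(np.asarray(R, dtype=float)).ravel()
    r, p1 = Q.shape
    if p1 != beta1_hat.size or Sigma1.shape != (p1, p1):
        raise ValueError("inconsistent contrast dimensions")
    if R.size != r:
        raise ValueError("R must have one entry per contrast row")
    if np.linalg.matrix_rank(Q) < r:
        raise ValueError("Q does not have full row rank")
    diff = Q @ beta1_hat - R
    M = Q @ Sigma1 @ Q.T
    try:
        sol = np.linalg.solve(M, diff)
    except np.linalg.LinAlgError:
        raise ValueError(
            "Q Sigma^(1) Q' is singular; reduce or re-parameterize the "
            "contrast") from None
    T = float(diff @ sol)
    p = float(stats.chi2.sf(T, df=r))
    return ContrastTest(S1=None if S1 is None else np.asarray(S1),
                        beta1_hat=beta1_hat, Sigma1=Sigma1, Q=Q, R=R,
                        T=T, df=r, p_value=p)
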