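"""Maximum-likelihood fitting of low-dimensional canonical-link GLMs.

These are the partial regressions at the heart of the split-and-smooth
estimator: the response is regressed on an intercept plus a small column
subset of the design.  Fitting is Newton-Raphson on the average negative
log-likelihood (equivalently IRLS for canonical links), with step halving.

A batched variant solves many such fits that share the sample but differ in
one design column, using batched linear algebra; it is the workhorse that
makes fitting all ``p`` per-predictor partial regressions of a split cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .families import Family, get_family

__all__ = ["GLMFit", "RankDeficiencyError", "negative_loglik", "fit_glm"]

logger = logging.getLogger(__name__)


class RankDeficiencyError(ValueError):
    """The intercept-augmented design is not full column rank."""


@dataclass
class GLMFit:
    """Result of a low-dimensional GLM fit.

    ``coefficients`` is ordered (intercept, then the predictor columns in the
    order supplied — ascending index order when called through the estimator).
    ``observed_information`` is (1/n) Xbar' V Xbar at the optimum.
    """

    coefficients: np.ndarray
    converged: bool
    iterations: int
    neg_loglik: float
    observed_information: np.ndarray


def negative_loglik(family, beta, X, y) -> float:
    """Average negative log-likelihood (1/n) sum{A(xi'beta) - yi xi'beta}.

    ``X`` must already contain the intercept column; the additive c(y) term is
    dropped as it does not depend on beta.
    """
    family = get_family(family)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or beta.shape != (X.shape[1],):
        raise ValueError(
            f"beta has length {beta.size} but X has {X.shape[1]} columns"
        )
    if y.shape != (X.shape[0],):
        raise ValueError("y length does not match number of rows of X")
    family.check_response(y)
    theta = X @ beta
    return float(np.mean(family.cumulant(theta) - y * theta))


def _check_rank(Xbar: np.ndarray) -> None:
    # a constant (zero-variance) predictor column duplicates the intercept
    sd = Xbar[:, 1:].std(axis=0) if Xbar.shape[1] > 1 else np.array([])
    if sd.size and np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise RankDeficiencyError(f"predictor column {j} is constant")
    if np.linalg.matrix_rank(Xbar) < Xbar.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")


def fit_glm(family, X, y, *, max_iter: int = 100, tol: float = 1e-8,
            check_rank: bool = True) -> GLMFit:
    """Fit a GLM of ``y`` on an intercept plus the columns of ``X``.

    Parameters
    ----------
    family : Family or str
    X : (n, k) array of predictors *without* intercept column (k may be 0).
    y : (n,) response.
    max_iter, tol : Newton iteration cap and max-abs coefficient-change
        convergence tolerance.
    check_rank : skip the O(nk^2) rank pre-check when the caller already
        guarantees full rank.

    Returns a :class:`GLMFit`; ``converged`` is False (never a silent wrong
    answer) if the iteration cap is hit, e.g. under logistic separation.
    """
    family = get_family(family)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X.size == 0:
        X = X.reshape(n, 0)
    if X.shape[0] != n:
        raise ValueError("X and y have inconsistent numbers of samples")
    family.check_response(y)
    if X.shape[1] + 1 >= n:
        raise ValueError(
            f"need n > k+1 for a {X.shape[1]}-predictor fit with n={n}"
        )
    Xbar = np.column_stack([np.ones(n), X])
    if check_rank:
        _check_rank(Xbar)

    beta = np.zeros(Xbar.shape[1])
    beta[0] = family.link(family.clamp_mean(np.mean(y)))
    beta, converged, n_iter, nll = _newton(family, Xbar, y, beta, max_iter, tol)

    mu = family.mean(Xbar @ beta)
    v = family.variance(mu)
    info = (Xbar.T * v) @ Xbar / n
    return GLMFit(
        coefficients=beta,
        converged=converged,
        iterations=n_iter,
        neg_loglik=nll,
        observed_information=info,
    )


def _newton(family: Family, Xbar, y, beta, max_iter, tol,
            max_halvings: int = 10):
    """Newton-Raphson with step halving on a single design."""
    n = y.shape[0]
    theta = Xbar @ beta
    nll = float(np.mean(family.cumulant(theta) - y * theta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = family.mean(theta)
        v = family.variance(mu)
        grad = Xbar.T @ (mu - y) / n
        H = (Xbar.T * v) @ Xbar / n
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(max_halvings + 1):
            cand = beta - step * delta
            theta_c = Xbar @ cand
            nll_c = float(np.mean(family.cumulant(theta_c) - y * theta_c))
            if nll_c <= nll + 1e-12:
                break
            step *= 0.5
        else:
            # could not decrease: stop at current iterate
            break
        moved = float(np.max(np.abs(cand - beta)))
        beta, theta, nll = cand, theta_c, nll_c
        if moved < tol:
            converged = True
            break
    return beta, converged, it, nll


def _newton_batched(family: Family, Xb, y, beta0, *, max_iter: int = 100,
                    tol: float = 1e-8, max_halvings: int = 10):
    """Newton-Raphson for ``m`` GLMs sharing the response but with distinct
    designs, solved simultaneously with batched linear algebra.

    Parameters
    ----------
    Xb : (m, n, k) stack of intercept-augmented designs.
    y : (n,) shared response.
    beta0 : (m, k) starting values.

    Returns (betas (m, k), converged (m,) bool, iterations int).

    Produces results identical (to solver tolerance) to fitting each design
    separately with :func:`fit_glm`; an equivalence test enforces this.
    """
    m, n, k = Xb.shape
    beta = beta0.copy()
    theta = np.einsum("mnk,mk->mn", Xb, beta)
    nll = np.mean(family.cumulant(theta) - y[None, :] * theta, axis=1)
    active = np.ones(m, dtype=bool)
    ok = np.ones(m, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        Xa = Xb[idx]
        th = theta[idx]
        mu = family.mean(th)
        v = family.variance(mu)
        # gradient (ma, k) and Hessian (ma, k, k) of the average NLL
        grad = np.einsum("mnk,mn->mk", Xa, mu - y[None, :]) / n
        WX = Xa * v[:, :, None]
        H = np.matmul(np.swapaxes(Xa, 1, 2), WX) / n
        try:
            delta = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # fall back per-model; singular ones are abandoned (ok=False)
            delta = np.empty_like(grad)
            for t in range(len(idx)):
                try:
                    delta[t] = np.linalg.solve(H[t], grad[t])
                except np.linalg.LinAlgError:
                    delta[t] = 0.0
                    ok[idx[t]] = False
                    active[idx[t]] = False
        step = np.ones(len(idx))
        cand = beta[idx] - delta
        theta_c = np.einsum("mnk,mk->mn", Xa, cand)
        nll_c = np.mean(family.cumulant(theta_c) - y[None, :] * theta_c, axis=1)
        for _ in range(max_halvings):
            worse = nll_c > nll[idx] + 1e-12
            if not np.any(worse):
                break
            step[worse] *= 0.5
            cand[worse] = beta[idx[worse]] - step[worse, None] * delta[worse]
            theta_c[worse] = np.einsum(
                "mnk,mk->mn", Xa[worse], cand[worse]
            )
            nll_c[worse] = np.mean(
                family.cumulant(theta_c[worse]) - y[None, :] * theta_c[worse],
                axis=1,
            )
        still_worse = nll_c > nll[idx] + 1e-12
        if np.any(still_worse):
            # cannot decrease: freeze those models at the current iterate
            cand[still_worse] = beta[idx[still_worse]]
            theta_c[still_worse] = theta[idx[still_worse]]
            nll_c[still_worse] = nll[idx[still_worse]]
            ok[idx[still_worse]] = False
            active[idx[still_worse]] = False
        moved = np.max(np.abs(cand - beta[idx]), axis=1)
        beta[idx] = cand
        theta[idx] = theta_c
        nll[idx] = nll_c
        done = moved < tol
        active[idx[done]] = False
        if not np.any(active):
            break
    converged = ok & ~active
    return beta, converged, it
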