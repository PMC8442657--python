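"""Variable selection on the screening half of a split.

Every selector obeys the same contract: given the half-sample (X2, y2) it
returns an ascending set of 1-based predictor indices whose size respects a
hard cap, deterministically for identical inputs and seed.  The role of the
selected set in the wider procedure is only *sure screening* — it should
contain the active set with high probability — not selection consistency, so
moderate over-selection is harmless downstream.

Selectors
---------
``sis_screen``
    Sure independence screening: rank predictors by absolute standardized
    marginal association with the response and keep the top ``d``.  The
    default size ``d = floor(sqrt(n2))`` keeps the downstream partial
    regressions low-dimensional relative to the estimation half (the sparsity
    regime the procedure is designed for); the conventional, more liberal
    ``n2/log(n2)`` sizing can be requested explicitly.
``lasso_select`` / ``elastic_net_select``
    L1 / mixed-penalty GLM with the regularization weight chosen by K-fold
    cross-validated deviance.
``scad_select`` / ``mcp_select``
    One-step local linear approximation: re-solve a weighted L1 problem with
    weights given by the SCAD/MCP penalty derivative at the CV-lasso solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _coordinate_descent as cd
from .families import get_family

__all__ = [
    "SelectionResult", "sis_screen", "lasso_select", "elastic_net_select",
    "scad_select", "mcp_select", "get_selector", "default_screen_size",
    "default_size_cap",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """An ascending 1-based index set plus selector metadata."""

    selected: np.ndarray
    selector_name: str
    tuning: dict = field(default_factory=dict)

    def __post_init__(self):
        self.selected = np.asarray(sorted(set(int(j) for j in self.selected)),
                                   dtype=int)
        if self.selected.size and (self.selected.min() < 1):
            raise ValueError("predictor indices are 1-based; 0 is the intercept")


def default_screen_size(n2: int) -> int:
    """Default SIS target size, floor(sqrt(n2))."""
    return max(1, int(np.floor(np.sqrt(n2))))


def default_size_cap(n2: int, n1: int | None = None) -> int:
    """Hard cap |S| <= min(n1, n2)/3, keeping partial fits well-posed."""
    cap = n2 // 3
    if n1 is not None:
        cap = min(cap, n1 // 3)
    return max(1, cap)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, sd


def sis_screen(X, y, family, d: int | None = None, *,
               size_cap: int | None = None, rng=None,
               utility: str = "rank") -> SelectionResult:
    """Sure independence screening by absolute marginal association.

    Ranks predictors on column-standardized data and keeps the top ``d``;
    ties break by ascending index.  Marginal utilities:

    - ``"rank"`` (default): the standardized marginal score statistic with
      the response replaced by its ranks (a Spearman-type robust screen).
      For a binary response this gives the identical ranking to ``"score"``,
      and for gaussian data it is essentially the Pearson ranking; for
      heavy-tailed responses (a Poisson outcome whose other signals act as
      massive overdispersion) it retains screening power that raw-scale
      statistics lose.
    - ``"score"``: ``|x_j'(y - ybar)| / (||x_j|| sd(y))`` on the raw
      response scale.
    - ``"mle"``: magnitude of the slope of the single-covariate GLM of y on
      x_j (marginal maximum-likelihood screening).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    family = get_family(family)
    family.check_response(y)
    n2, p = X.shape
    if d is None:
        d = default_screen_size(n2)
    if d < 1:
        raise ValueError("screening size d must be >= 1")
    if d >= n2:
        raise ValueError(f"screening size d={d} must be < n2={n2}")
    cap = default_size_cap(n2) if size_cap is None else size_cap
    d_eff = min(d, p, cap)
    Xs, sd = _standardize(X)
    if utility in ("score", "rank"):
        yt = stats.rankdata(y) if utility == "rank" else y
        yc = yt - yt.mean()
        sdy = yt.std()
        denom = np.sqrt(n2) * (sdy if sdy > 0 else 1.0)
        score = np.abs(Xs.T @ yc) / denom
    elif utility == "mle":
        score = np.abs(_marginal_glm_slopes(Xs, y, family))
    else:
        raise ValueError(f"unknown SIS utility {utility!r}")
    score[sd == 0] = -np.inf  # constant columns carry no signal
    order = np.lexsort((np.arange(p), -score))
    sel = np.sort(order[:d_eff]) + 1
    return SelectionResult(sel, "sis", {"d": int(d), "size_cap": int(cap),
                                        "utility": utility})


def _marginal_glm_slopes(Xs, y, family) -> np.ndarray:
    """Slopes of the p single-covariate GLM fits (batched Newton)."""
    from .glm import _newton_batched  # deferred: avoids an import cycle

    n2, p = Xs.shape
    Xb = np.empty((p, n2, 2))
    Xb[:, :, 0] = 1.0
    Xb[:, :, 1] = Xs.T
    init = np.zeros((p, 2))
    init[:, 0] = family.link(family.clamp_mean(np.mean(y)))
    betas, conv, _ = _newton_batched(family, Xb, y, init,
                                     max_iter=50, tol=1e-6)
    slopes = betas[:, 1]
    slopes[~conv] = np.inf  # a diverging marginal fit = perfect separation
    return slopes


def _cv_enet(X, y, family_name, alpha, n_folds, rng, n_lambda,
             lambda_min_ratio, dfmax=None, rule="1se"):
    """Cross-validated elastic-net path; returns (lams, best_l, b0s, betas)
    with the path fit on the full half-sample."""
    n, p = X.shape
    grad0 = cd.null_deviance_gradient(X, y, family_name)
    lam_max = float(np.max(grad0)) / max(alpha, 1e-3)
    if lam_max <= 0:
        lam_max = 1e-3
    lams = cd.make_lambda_path(lam_max, n_lambda, lambda_min_ratio)
    # selection-grade solver settings: supports are insensitive to the last
    # digits of the coefficients, so the IRLS loop can stop early
    solver = dict(tol_cd=1e-6, tol_outer=3e-4, max_outer=5)
    b0s, betas = cd.enet_path_fit(X, y, family_name, alpha=alpha, lams=lams,
                                  dfmax=dfmax, **solver)

    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    dev = np.zeros((n_folds, len(lams)))
    for f in range(n_folds):
        tr = folds != f
        te = ~tr
        b0f, betf = cd.enet_path_fit(X[tr], y[tr], family_name,
                                     alpha=alpha, lams=lams, dfmax=dfmax,
                                     **solver)
        for l in range(len(lams)):
            mu = cd.predict_mean(b0f[l], betf[l], X[te], family_name)
            dev[f, l] = cd.deviance(y[te], mu, family_name)
    mean_dev = dev.mean(axis=0)
    min_l = int(np.argmin(mean_dev))
    if rule == "min":
        best_l = min_l
    elif rule == "1se":
        # largest penalty whose CV deviance is within one standard error of
        # the minimum (the conventional parsimonious choice for selection)
        se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best_l = int(np.argmax(mean_dev <= mean_dev[min_l] + se[min_l]))
    else:
        raise ValueError(f"unknown CV rule {rule!r}")
    return lams, best_l, b0s, betas


def _support_from_coef(beta_std, cap, name, tuning):
    nz = np.flatnonzero(beta_std != 0)
    if nz.size == 0:
        return None
    if nz.size > cap:
        keep = nz[np.argsort(-np.abs(beta_std[nz]), kind="stable")[:cap]]
        nz = np.sort(keep)
    return SelectionResult(nz + 1, name, tuning)


def _penalized_select(X, y, family, alpha, name, *, n_folds=10, rng=None,
                      size_cap=None, n_lambda=30, lambda_min_ratio=0.01,
                      rule="1se", reweight=None):
    family = get_family(family)
    family.check_response(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n2, p = X.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(rng)
    cap = default_size_cap(n2) if size_cap is None else size_cap
    Xs, sd = _standardize(X)
    # the support is truncated to the cap anyway, so penalties weak enough
    # to overshoot it by more than a margin are never useful
    dfmax = min(p, cap + 10)
    lams, best_l, b0s, betas = _cv_enet(Xs, y, family.name, alpha, n_folds,
                                        rng, n_lambda, lambda_min_ratio,
                                        dfmax=dfmax, rule=rule)
    beta_best = betas[best_l]
    tuning = {"lambda": float(lams[best_l]), "alpha": float(alpha),
              "cv_folds": int(n_folds), "cv_rule": rule,
              "size_cap": int(cap)}
    if reweight is not None:
        pf = reweight(np.abs(beta_best), lams[best_l])
        b0s1, betas1 = cd.enet_path_fit(
            Xs, y, family.name, alpha=1.0, lams=np.array([lams[best_l]]),
            pf=pf, beta_init=beta_best.copy(), b0_init=float(b0s[best_l]))
        beta_best = betas1[0]
    res = _support_from_coef(beta_best, cap, name, tuning)
    if res is None:
        # empty support at the chosen lambda: fall back to the strongest
        # coefficient seen anywhere along the path
        logger.warning("%s: empty support at chosen lambda; "
                       "falling back to the strongest path coefficient", name)
        flat = np.abs(betas).max(axis=0)
        j = int(np.argmax(flat))
        res = SelectionResult(np.array([j + 1]), name, tuning)
    return res


def lasso_select(X, y, family, *, n_folds=10, rng=None, size_cap=None,
                 n_lambda=30, lambda_min_ratio=0.01,
                 rule="1se") -> SelectionResult:
    """L1-penalized GLM with lambda chosen by cross-validated deviance
    (``rule``: "1se" for the parsimonious one-standard-error choice,
    "min" for the deviance minimizer)."""
    return _penalized_select(X, y, family, 1.0, "lasso", n_folds=n_folds,
                             rng=rng, size_cap=size_cap, n_lambda=n_lambda,
                             lambda_min_ratio=lambda_min_ratio, rule=rule)


def elastic_net_select(X, y, family, *, mixing=0.5, n_folds=10, rng=None,
                       size_cap=None, n_lambda=30, lambda_min_ratio=0.01,
                       rule="1se") -> SelectionResult:
    """Elastic-net penalized GLM (``mixing`` is the L1 share alpha)."""
    res = _penalized_select(X, y, family, float(mixing), "elasticnet",
                            n_folds=n_folds, rng=rng, size_cap=size_cap,
                            n_lambda=n_lambda,
                            lambda_min_ratio=lambda_min_ratio, rule=rule)
    return res


def _scad_weights(a=3.7):
    def w(absbeta, lam):
        pf = np.where(
            absbeta <= lam, 1.0,
            np.maximum(a * lam - absbeta, 0.0) / ((a - 1.0) * lam))
        return pf
    return w


def _mcp_weights(a=3.0):
    def w(absbeta, lam):
        return np.maximum(1.0 - absbeta / (a * lam), 0.0)
    return w


def scad_select(X, y, family, *, a=3.7, n_folds=10, rng=None, size_cap=None,
                n_lambda=30, lambda_min_ratio=0.01,
                rule="1se") -> SelectionResult:
    """SCAD by one-step local linear approximation from the CV-lasso fit."""
    return _penalized_select(X, y, family, 1.0, "scad", n_folds=n_folds,
                             rng=rng, size_cap=size_cap, n_lambda=n_lambda,
                             lambda_min_ratio=lambda_min_ratio, rule=rule,
                             reweight=_scad_weights(a))


def mcp_select(X, y, family, *, a=3.0, n_folds=10, rng=None, size_cap=None,
               n_lambda=30, lambda_min_ratio=0.01,
               rule="1se") -> SelectionResult:
    """MCP by one-step local linear approximation from the CV-lasso fit."""
    return _penalized_select(X, y, family, 1.0, "mcp", n_folds=n_folds,
                             rng=rng, size_cap=size_cap, n_lambda=n_lambda,
                             lambda_min_ratio=lambda_min_ratio, rule=rule,
                             reweight=_mcp_weights(a))


_SELECTORS = {
    "sis": sis_screen,
    "lasso": lasso_select,
    "elasticnet": elastic_net_select,
    "scad": scad_select,
    "mcp": mcp_select,
}


def get_selector(name: str):
    """Selector lookup by CLI/config name."""
    try:
        return _SELECTORS[name]
    except KeyError:
        raise ValueError(
            f"unknown selector {name!r}; choose from {sorted(_SELECTORS)}"
        ) from None
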