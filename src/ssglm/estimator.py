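"""Split-and-smooth estimation for high-dimensional GLMs.

One split: draw an estimation half D1 of size ``n1 = round(q*n)`` without
replacement, run a screening selector on the other half D2 to get a small
set S, then for every predictor ``j`` fit the low-dimensional partial GLM of
``y`` on ``{intercept} ∪ S ∪ {j}`` using D1 and keep the coefficient of
``j``.  For ``j`` in S (and the intercept, with the convention that S+0 = S)
a single fit on S supplies the coefficient.  Smoothing: average the per-split
coefficient vectors over B independent random splits.

The per-split work for all p partial regressions is done by a batched Newton
solver; every split b draws from an independently derived RNG stream, so the
result is invariant to execution order and parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .data import Dataset
from .families import get_family
from .glm import RankDeficiencyError, _newton_batched, fit_glm
from .selection import default_size_cap, get_selector

__all__ = ["SSGLMConfig", "SplitRecord", "SSGLMFit", "SubvectorFit",
           "one_split_estimate", "ssglm_fit", "subvector_fit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SSGLMConfig:
    """Configuration of the split-and-smooth procedure.

    B: number of random splits (500 is a reasonable default for estimation;
       use ~1000 for final inference runs).
    q: estimation-half proportion, n1 = round(q*n).
    selector: selector name ("sis", "lasso", "elasticnet", "scad", "mcp")
       or a callable with the selector signature.
    selector_kwargs: extra keyword arguments for the selector (e.g. ``d``,
       ``n_folds``).
    seed: master seed; split b uses the derived stream ``[seed, b]``.
    n_jobs: joblib workers for the loop over splits (threads; results are
       independent of n_jobs).
    max_redraws: for binomial data, a split whose halves do not both contain
       both response classes is redrawn up to this many times.
    """

    B: int = 500
    q: float = 0.5
    selector: object = "sis"
    selector_kwargs: dict = field(default_factory=dict)
    seed: int = 0
    n_jobs: int = 1
    max_redraws: int = 100
    glm_max_iter: int = 100
    glm_tol: float = 1e-8

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def n1(self, n: int) -> int:
        return int(round(self.q * n))


@dataclass
class SplitRecord:
    """Everything retained from one random split."""

    b: int
    J: np.ndarray                 # (n,) bool, True when sample i is in D1
    selection: object             # SelectionResult
    beta_tilde: np.ndarray        # (p+1,), NaN where the partial fit failed
    converged: np.ndarray         # (p+1,) bool


@dataclass
class SSGLMFit:
    """Smoothed coefficients plus the per-split records behind them."""

    beta_hat: np.ndarray          # (p+1,), index 0 = intercept
    splits: list
    config: SSGLMConfig
    n: int
    p: int

    @property
    def n1(self) -> int:
        return self.config.n1(self.n)

    @property
    def J_matrix(self) -> np.ndarray:
        """(B, n) split-membership indicators."""
        return np.array([s.J for s in self.splits])

    @property
    def beta_tilde_matrix(self) -> np.ndarray:
        """(B, p+1) one-time estimates (NaN marks per-split failures)."""
        return np.array([s.beta_tilde for s in self.splits])

    @property
    def selection_frequency(self) -> np.ndarray:
        """(p+1,) fraction of splits selecting each predictor (1.0 for the
        intercept, which is in every partial model)."""
        counts = np.zeros(self.p + 1)
        counts[0] = len(self.splits)
        for s in self.splits:
            counts[s.selection.selected] += 1
        return counts / len(self.splits)

    @property
    def n_used(self) -> np.ndarray:
        """(p+1,) number of splits contributing to each coefficient."""
        return np.sum(~np.isnan(self.beta_tilde_matrix), axis=0)


@dataclass
class SubvectorFit:
    """Smoothed estimate of a fixed coefficient subset (one joint fit per
    split on S1 ∪ S instead of p separate partial fits)."""

    S1: np.ndarray                # 1-based predictor indices, caller's order
    beta1_hat: np.ndarray         # (p1,)
    beta_tilde: np.ndarray        # (B, p1) per-split subvector estimates
    J_matrix: np.ndarray          # (B, n)
    splits_meta: list             # per-split SelectionResult
    config: SSGLMConfig
    n: int

    @property
    def n1(self) -> int:
        return self.config.n1(self.n)


def _draw_split(data: Dataset, n1: int, rng, max_redraws: int) -> np.ndarray:
    """Sample D1 without replacement; for binomial data redraw until both
    halves contain both classes."""
    n = data.n
    for attempt in range(max_redraws + 1):
        idx1 = rng.choice(n, size=n1, replace=False)
        if data.family.name != "binomial":
            return idx1
        mask = np.zeros(n, dtype=bool)
        mask[idx1] = True
        y1, y2 = data.y[mask], data.y[~mask]
        if 0 < y1.sum() < y1.size and 0 < y2.sum() < y2.size:
            if attempt:
                logger.info("redrew split %d time(s) for class balance",
                            attempt)
            return idx1
    raise RuntimeError(
        "could not draw a split with both response classes in both halves"
    )


def _run_selector(config: SSGLMConfig, X2, y2, family, rng, size_cap):
    selector = config.selector
    if isinstance(selector, str):
        selector = get_selector(selector)
    return selector(X2, y2, family, rng=rng, size_cap=size_cap,
                    **config.selector_kwargs)


def one_split_estimate(data: Dataset, config: SSGLMConfig, rng, *,
                       idx1=None) -> SplitRecord:
    """Run a single split: draw D1/D2, select on D2, fit all p partial
    regressions on D1.  ``rng`` is a numpy Generator dedicated to this split.
    ``idx1`` forces the estimation-half membership (diagnostics/tests).
    """
    n, p = data.n, data.p
    n1 = config.n1(n)
    n2 = n - n1
    if idx1 is None:
        idx1 = _draw_split(data, n1, rng, config.max_redraws)
    else:
        idx1 = np.asarray(idx1, dtype=int)
        if idx1.size != n1:
            raise ValueError(f"idx1 must have n1={n1} entries")
    J = np.zeros(n, dtype=bool)
    J[idx1] = True

    cap = default_size_cap(n2, n1)
    sel = _run_selector(config, data.X[~J], data.y[~J], data.family, rng, cap)
    S = sel.selected                      # ascending, 1-based
    if S.size + 2 > n1:
        raise RuntimeError(
            f"selected set of size {S.size} too large for n1={n1}"
        )

    X1 = data.X[J]
    y1 = data.y[J]
    beta_tilde = np.full(p + 1, np.nan)
    converged = np.zeros(p + 1, dtype=bool)

    # single fit on S covers the intercept and every j in S (S+j = S there)
    base_beta = None
    try:
        base = fit_glm(data.family, X1[:, S - 1], y1, check_rank=False,
                       max_iter=config.glm_max_iter, tol=config.glm_tol)
        base_beta = base.coefficients
        if base.converged:
            beta_tilde[0] = base_beta[0]
            beta_tilde[S] = base_beta[1:]
            converged[0] = True
            converged[S] = True
        else:
            logger.info("base fit on S did not converge; its coefficients "
                        "are recorded as missing for this split")
    except (RankDeficiencyError, np.linalg.LinAlgError) as exc:
        logger.warning("split: base fit failed (%s)", exc)

    rest = np.setdiff1d(np.arange(1, p + 1), S)
    if rest.size:
        m = S.size + 2
        Xb = np.empty((rest.size, n1, m))
        Xb[:, :, 0] = 1.0
        Xb[:, :, 1:m - 1] = X1[:, S - 1][None, :, :]
        Xb[:, :, m - 1] = X1[:, rest - 1].T
        init = np.zeros((rest.size, m))
        if base_beta is not None:
            init[:, :m - 1] = base_beta
        else:
            fam = get_family(data.family)
            init[:, 0] = fam.link(fam.clamp_mean(np.mean(y1)))
        betas, conv, _ = _newton_batched(
            data.family, Xb, y1, init,
            max_iter=config.glm_max_iter, tol=config.glm_tol)
        # coefficient of predictor j is the appended (last) column; GLM fits
        # are invariant to column order, so this equals the ascending-order fit
        beta_tilde[rest] = np.where(conv, betas[:, -1], np.nan)
        converged[rest] = conv
    return SplitRecord(b=-1, J=J, selection=sel, beta_tilde=beta_tilde,
                       converged=converged)


def _split_rng(seed: int, b: int):
    """Independent, order-invariant stream for split b."""
    return np.random.default_rng([seed, b])


def ssglm_fit(data: Dataset, config: SSGLMConfig) -> SSGLMFit:
    """Run B independent splits and average the one-time estimates.

    Raises ``RuntimeError`` if more than 10% of splits fail entirely.
    Coefficients missing in more than 20% of splits are flagged in the log;
    each coefficient averages over the splits where its fit succeeded.
    """
    n, p = data.n, data.p

    def run(b):
        rec = one_split_estimate(data, config, _split_rng(config.seed, b))
        rec.b = b
        return rec

    if config.n_jobs != 1:
        splits = Parallel(n_jobs=config.n_jobs, backend="threading")(
            delayed(run)(b) for b in range(config.B))
    else:
        splits = [run(b) for b in range(config.B)]

    Btilde = np.array([s.beta_tilde for s in splits])
    dead = np.all(np.isnan(Btilde), axis=1)
    if dead.sum() > 0.1 * config.B:
        raise RuntimeError(
            f"{int(dead.sum())}/{config.B} splits failed entirely; "
            "check the family/selector configuration"
        )
    with np.errstate(invalid="ignore"):
        beta_hat = np.nanmean(Btilde, axis=0)
    miss = np.isnan(Btilde).mean(axis=0)
    flagged = np.flatnonzero(miss > 0.2)
    if flagged.size:
        logger.warning(
            "coefficients %s missing in >20%% of splits", flagged[:20])
    return SSGLMFit(beta_hat=beta_hat, splits=list(splits), config=config,
                    n=n, p=p)


def subvector_fit(data: Dataset, S1, config: SSGLMConfig) -> SubvectorFit:
    """Smoothed estimator of a fixed subvector (Algorithm: per split, one
    GLM of y on S1 ∪ S; average the S1 coordinates over splits).

    ``S1`` is a list of 1-based predictor indices, kept in the caller's
    order in all outputs.  With the same seed the splits (and selections)
    are identical to :func:`ssglm_fit`.
    """
    S1 = np.asarray([int(j) for j in S1])
    if S1.size < 1 or np.unique(S1).size != S1.size:
        raise ValueError("S1 must be a non-empty set of distinct predictors")
    if S1.min() < 1 or S1.max() > data.p:
        raise ValueError("S1 indices must be within 1..p")
    n = data.n
    n1 = config.n1(n)
    n2 = n - n1

    def run(b):
        rng = _split_rng(config.seed, b)
        idx1 = _draw_split(data, n1, rng, config.max_redraws)
        J = np.zeros(n, dtype=bool)
        J[idx1] = True
        cap = default_size_cap(n2, n1)
        sel = _run_selector(config, data.X[~J], data.y[~J], data.family,
                            rng, cap)
        union = np.union1d(S1, sel.selected)        # ascending
        pos = 1 + np.searchsorted(union, S1)        # coefficient positions
        row = np.full(S1.size, np.nan)
        try:
            fit = fit_glm(data.family, data.X[J][:, union - 1], data.y[J],
                          check_rank=False, max_iter=config.glm_max_iter,
                          tol=config.glm_tol)
            if fit.converged:
                row = fit.coefficients[pos]
        except (RankDeficiencyError, np.linalg.LinAlgError) as exc:
            logger.warning("subvector split %d failed (%s)", b, exc)
        return J, row, sel

    if config.n_jobs != 1:
        out = Parallel(n_jobs=config.n_jobs, backend="threading")(
            delayed(run)(b) for b in range(config.B))
    else:
        out = [run(b) for b in range(config.B)]

    Jmat = np.array([o[0] for o in out])
    Btilde = np.array([o[1] for o in out])
    dead = np.all(np.isnan(Btilde), axis=1)
    if dead.sum() > 0.1 * config.B:
        raise RuntimeError(
            f"{int(dead.sum())}/{config.B} subvector splits failed")
    with np.errstate(invalid="ignore"):
        beta1_hat = np.nanmean(Btilde, axis=0)
    return SubvectorFit(S1=S1, beta1_hat=beta1_hat, beta_tilde=Btilde,
                        J_matrix=Jmat, splits_meta=[o[2] for o in out],
                        config=config, n=n)
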