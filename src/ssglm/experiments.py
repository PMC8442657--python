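"""Replicated simulation studies: estimation accuracy, coverage, power,
type-I error, contrast rejection rates, and the split-proportion and
variance-convergence diagnostics.

Each study realizes the design truth once from the master seed, then draws K
independent datasets and runs the full split-and-smooth fit plus inference
per draw.  Replicate k uses the derived stream [seed, k+1]; the fit inside a
replicate derives its own split streams from a seed drawn there, so studies
are reproducible bit-for-bit from (design, K, config, seed).  Monte-Carlo
(binomial) standard errors accompany every estimated probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import SSGLMConfig, ssglm_fit, subvector_fit
from .inference import (bias_corrected_variance, ij_variance, inference_table,
                        subvector_covariance, wald_contrast_test)
from .synth import RealizedDesign, SimulationDesign

__all__ = ["MetricsTable", "run_replicates", "split_proportion_study",
           "variance_convergence_study", "power_type1_study",
           "contrast_study"]

logger = logging.getLogger(__name__)


def _realize(design, seed) -> RealizedDesign:
    if isinstance(design, SimulationDesign):
        return design.realize(np.random.default_rng([seed, 0]))
    return design


def _binom_se(phat, K):
    return np.sqrt(np.maximum(phat * (1 - phat), 0.0) / K)


@dataclass
class MetricsTable:
    """Aggregated study output.

    ``per_coefficient`` has one row per coefficient (0 = intercept):
    truth, bias, se (mean estimated SE), sd (empirical SD of the smoothed
    estimate), coverage, sel_freq, mse, reject (rate of p < alpha).
    Raw per-replicate arrays are retained for follow-up summaries.
    """

    per_coefficient: pd.DataFrame
    S_star: np.ndarray
    truth: np.ndarray
    K: int
    alpha: float
    n_failed: int
    estimates: np.ndarray = field(repr=False)   # (K, p+1)
    ses: np.ndarray = field(repr=False)         # (K, p+1)
    pvalues: np.ndarray = field(repr=False)     # (K, p+1)
    covered: np.ndarray = field(repr=False)     # (K, p+1) bool
    sel_freq: np.ndarray = field(repr=False)    # (K, p+1)
    model_sizes: np.ndarray = field(repr=False)  # (K,)

    @property
    def noise_index(self) -> np.ndarray:
        p = self.truth.size - 1
        return np.setdiff1d(np.arange(1, p + 1), self.S_star)

    @property
    def mse_avg(self) -> float:
        """Average over the p predictors of the per-coefficient MSE."""
        mse = self.per_coefficient["mse"].to_numpy()[1:]
        return float(np.mean(mse))

    @property
    def avg_coverage(self) -> float:
        """Coverage averaged over all predictors and replicates."""
        return float(np.mean(self.covered[:, 1:]))

    @property
    def noise_coverage(self) -> float:
        return float(np.mean(self.covered[:, self.noise_index]))

    @property
    def avg_type1(self) -> float:
        """Rejection rate at alpha averaged over noise coefficients."""
        return float(np.mean(self.pvalues[:, self.noise_index] < self.alpha))

    @property
    def power(self) -> np.ndarray:
        """Per-signal rejection rate at alpha (active-set order)."""
        return np.mean(self.pvalues[:, self.S_star] < self.alpha, axis=0)

    @property
    def avg_model_size(self) -> float:
        return float(np.mean(self.model_sizes))


def run_replicates(design, config: SSGLMConfig, K: int, seed: int,
                   alpha: float = 0.05) -> MetricsTable:
    """K full simulate-fit-infer replicates of one design."""
    if K < 2:
        raise ValueError("K must be >= 2")
    realized = _realize(design, seed)
    p = realized.design.p
    truth = realized.beta
    rows_est, rows_se, rows_p, rows_cov, rows_sf, sizes = [], [], [], [], [], []
    n_failed = 0
    for k in range(K):
        rng = np.random.default_rng([seed, k + 1])
        data = realized.sample(rng)
        cfg = replace(config, seed=int(rng.integers(2**31)))
        try:
            fit = ssglm_fit(data, cfg)
            tab = inference_table(fit, alpha=alpha)
        except RuntimeError as exc:
            n_failed += 1
            logger.warning("replicate %d failed: %s", k, exc)
            continue
        est = tab["estimate"].to_numpy()
        rows_est.append(est)
        rows_se.append(tab["se"].to_numpy())
        rows_p.append(tab["pvalue"].to_numpy())
        rows_cov.append((tab["ci_lo"].to_numpy() <= truth)
                        & (truth <= tab["ci_hi"].to_numpy()))
        rows_sf.append(tab["sel_freq"].to_numpy())
        sizes.append(np.mean([s.selection.selected.size for s in fit.splits]))
    if len(rows_est) < 2:
        raise RuntimeError("fewer than 2 replicates succeeded")
    K_eff = len(rows_est)
    est = np.array(rows_est)
    ses = np.array(rows_se)
    pvals = np.array(rows_p)
    cov = np.array(rows_cov)
    sf = np.array(rows_sf)
    coverage = cov.mean(axis=0)
    per = pd.DataFrame({
        "index": np.arange(p + 1),
        "truth": truth,
        "bias": est.mean(axis=0) - truth,
        "se": ses.mean(axis=0),
        "sd": est.std(axis=0, ddof=1),
        "coverage": coverage,
        "coverage_mc_se": _binom_se(coverage, K_eff),
        "sel_freq": sf.mean(axis=0),
        "mse": np.mean((est - truth) ** 2, axis=0),
        "reject": np.mean(pvals < alpha, axis=0),
    })
    return MetricsTable(per_coefficient=per, S_star=realized.S_star,
                        truth=truth, K=K_eff, alpha=alpha, n_failed=n_failed,
                        estimates=est, ses=ses, pvalues=pvals, covered=cov,
                        sel_freq=sf, model_sizes=np.array(sizes))


def split_proportion_study(design, q_grid, config: SSGLMConfig, K: int,
                           seed: int) -> pd.DataFrame:
    """Average MSE over all predictors at each split proportion q."""
    rows = []
    for q in q_grid:
        mt = run_replicates(design, replace(config, q=float(q)), K, seed)
        rows.append({"q": float(q), "mse_avg": mt.mse_avg,
                     "avg_coverage": mt.avg_coverage})
    return pd.DataFrame(rows)


def variance_convergence_study(design, B_grid, config: SSGLMConfig, K: int,
                               seed: int) -> pd.DataFrame:
    """Mean (over signal coefficients) of V_j and V_j^B versus the empirical
    variance of the smoothed estimates, at each number of splits B.

    One run at max(B_grid) per replicate; smaller B values reuse its first B
    splits (splits are i.i.d., so the truncation is a valid B-split run).
    """
    B_grid = sorted(int(b) for b in B_grid)
    B_max = B_grid[-1]
    realized = _realize(design, seed)
    sig = realized.S_star
    fits = []
    for k in range(K):
        rng = np.random.default_rng([seed, k + 1])
        data = realized.sample(rng)
        cfg = replace(config, B=B_max, seed=int(rng.integers(2**31)))
        fits.append(ssglm_fit(data, cfg))
    rows = []
    for B in B_grid:
        V_sig, VB_sig, est = [], [], []
        for fit in fits:
            J = fit.J_matrix[:B]
            Bt = fit.beta_tilde_matrix[:B]
            V = ij_variance(J, Bt, fit.n1)
            VB = bias_corrected_variance(V, J, Bt, fit.n1)
            V_sig.append(V[sig])
            VB_sig.append(VB[sig])
            est.append(np.nanmean(Bt, axis=0)[sig])
        emp = np.var(np.array(est), axis=0, ddof=1)
        rows.append({
            "B": B,
            "V_mean": float(np.mean(V_sig)),
            "VB_mean": float(np.mean(VB_sig)),
            "empirical_var": float(np.mean(emp)),
        })
    return pd.DataFrame(rows)


def power_type1_study(design, config: SSGLMConfig, K: int, seed: int,
                      alpha: float = 0.05):
    """Per-signal power and average type-I error over noise coefficients."""
    mt = run_replicates(design, config, K, seed, alpha=alpha)
    power = mt.power
    out = pd.DataFrame({
        "index": mt.S_star,
        "truth": mt.truth[mt.S_star],
        "power": power,
        "power_mc_se": _binom_se(power, mt.K),
    })
    return out, mt.avg_type1, mt


def contrast_study(design, contrasts, S1, config: SSGLMConfig, K: int,
                   seed: int, alpha: float = 0.05) -> pd.DataFrame:
    """Rejection rate of each Wald contrast over K replicates.

    ``contrasts``: list of (label, Q, R); Q rows act on the S1 coordinates
    in the order given.
    """
    realized = _realize(design, seed)
    rej = np.zeros(len(contrasts))
    K_eff = 0
    for k in range(K):
        rng = np.random.default_rng([seed, k + 1])
        data = realized.sample(rng)
        cfg = replace(config, seed=int(rng.integers(2**31)))
        try:
            sub = subvector_fit(data, S1, cfg)
            Sigma1 = subvector_covariance(sub)
        except RuntimeError as exc:
            logger.warning("contrast replicate %d failed: %s", k, exc)
            continue
        K_eff += 1
        for c, (_, Q, R) in enumerate(contrasts):
            t = wald_contrast_test(sub.beta1_hat, Sigma1, Q, R)
            rej[c] += t.p_value < alpha
    if K_eff < 2:
        raise RuntimeError("fewer than 2 contrast replicates succeeded")
    rate = rej / K_eff
    return pd.DataFrame({
        "contrast": [c[0] for c in contrasts],
        "rejection_rate": rate,
        "mc_se": _binom_se(rate, K_eff),
        "K": K_eff,
    })
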