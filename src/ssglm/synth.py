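"""Synthetic data for high-dimensional GLM simulation studies.

Rows of the design are drawn from a zero-mean multivariate normal with one of
three correlation structures — identity, AR(1) (Sigma_ij = rho^|i-j|) or
compound symmetry (Sigma_ij = rho for i != j) — the sparse coefficient vector
is built from a coefficient rule (fixed values or a uniform band with
optional random signs) on a fixed or random active set, and the outcome is
generated from the gaussian, logistic or Poisson model with canonical link.

A design is *realized* once (active set, effects, covariance factor frozen)
and then sampled any number of times; simulation tables in this field report
one realization sampled over many replicates.  For the poisson family the
predictors are truncated at +-3 SD by default so that exp(x'beta) cannot
overflow for the effect sizes used here.

Presets ``example1`` .. ``example5`` encode the printed designs of the
reference simulation studies (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .families import get_family

__all__ = ["SimulationDesign", "RealizedDesign", "make_covariance",
           "simulate_dataset", "example1", "example2", "example3",
           "example4", "example5", "get_preset", "PRESETS"]


def make_covariance(corr: str, p: int, rho: float = 0.0) -> np.ndarray:
    """Predictor covariance matrix for one of the named structures."""
    if corr == "identity":
        return np.eye(p)
    if corr == "ar1":
        if not -1.0 < rho < 1.0:
            raise ValueError("ar1 requires rho in (-1, 1)")
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if corr == "cs":
        if not -1.0 / (p - 1) < rho < 1.0:
            raise ValueError(f"cs requires rho in (-1/{p-1}, 1)")
        return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)
    raise ValueError(f"unknown correlation structure {corr!r}")


@dataclass(frozen=True)
class SimulationDesign:
    """Generative truth for one simulation study.

    coef_rule: ("uniform_band", lo, hi, random_sign) draws |beta| ~ U[lo, hi]
        with independent fair-coin signs when random_sign; ("fixed", values)
        uses the given values in active-set order.
    active_rule: ("random", s0) draws s0 distinct indices; ("fixed", indices)
        uses the given 1-based indices.
    truncate_x: clip X at +-truncate_x SD; defaults to 3 for poisson
        (overflow control), off otherwise.
    """

    n: int
    p: int
    family: str
    corr: str = "identity"
    rho: float = 0.0
    coef_rule: tuple = ("uniform_band", 0.5, 1.5, True)
    active_rule: tuple = ("random", 5)
    intercept: float = 0.0
    truncate_x: float | None = None

    def __post_init__(self):
        get_family(self.family)
        s0 = (len(self.active_rule[1]) if self.active_rule[0] == "fixed"
              else int(self.active_rule[1]))
        if s0 >= self.n:
            raise ValueError("s0 must be smaller than n")
        make_covariance(self.corr, self.p, self.rho)  # validates rho

    @property
    def s0(self) -> int:
        return (len(self.active_rule[1]) if self.active_rule[0] == "fixed"
                else int(self.active_rule[1]))

    def realize(self, rng) -> "RealizedDesign":
        """Freeze the active set and effect sizes."""
        rng = np.random.default_rng(rng)
        if self.active_rule[0] == "fixed":
            S_star = np.asarray(sorted(self.active_rule[1]), dtype=int)
            if S_star.min() < 1 or S_star.max() > self.p:
                raise ValueError("fixed active indices must lie in 1..p")
        elif self.active_rule[0] == "random":
            S_star = np.sort(rng.choice(self.p, size=self.s0, replace=False)
                             + 1)
        else:
            raise ValueError(f"unknown active rule {self.active_rule[0]!r}")
        beta = np.zeros(self.p + 1)
        beta[0] = self.intercept
        if self.coef_rule[0] == "fixed":
            vals = np.asarray(self.coef_rule[1], dtype=float)
            if vals.size != S_star.size:
                raise ValueError("fixed coefficient rule length != s0")
        elif self.coef_rule[0] == "uniform_band":
            _, lo, hi, random_sign = self.coef_rule
            vals = rng.uniform(lo, hi, size=S_star.size)
            if random_sign:
                vals *= rng.choice([-1.0, 1.0], size=S_star.size)
        else:
            raise ValueError(f"unknown coefficient rule {self.coef_rule[0]!r}")
        beta[S_star] = vals
        chol = np.linalg.cholesky(make_covariance(self.corr, self.p, self.rho))
        return RealizedDesign(design=self, S_star=S_star, beta=beta,
                              chol=chol)


@dataclass
class RealizedDesign:
    """A design with frozen truth: sample (X, y) replicates from it."""

    design: SimulationDesign
    S_star: np.ndarray            # ascending 1-based active indices
    beta: np.ndarray              # (p+1,), index 0 = intercept
    chol: np.ndarray = field(repr=False)

    @property
    def beta_active(self) -> np.ndarray:
        return self.beta[self.S_star]

    def sample(self, rng) -> Dataset:
        rng = np.random.default_rng(rng)
        d = self.design
        fam = get_family(d.family)
        X = rng.standard_normal((d.n, d.p)) @ self.chol.T
        trunc = d.truncate_x
        if trunc is None and d.family == "poisson":
            trunc = 3.0
        if trunc is not None:
            X = np.clip(X, -trunc, trunc)
        eta = self.beta[0] + X @ self.beta[1:]
        if d.family == "gaussian":
            y = eta + rng.standard_normal(d.n)
        elif d.family == "binomial":
            y = (rng.random(d.n) < fam.mean(eta)).astype(float)
        else:
            mu = np.exp(np.clip(eta, -30, 30))
            if np.any(mu > 1e8):
                raise ValueError(
                    "poisson mean overflow after truncation; use smaller "
                    "coefficients or a tighter truncate_x")
            y = rng.poisson(mu).astype(float)
        return Dataset(X, y, d.family)


def simulate_dataset(design, rng):
    """Draw one dataset (plus its frozen truth) in a single call.

    Accepts a :class:`SimulationDesign` (realizes it first with the same
    stream) or an already-:class:`RealizedDesign`.  Returns
    ``(Dataset, beta (p+1,), S_star)``.
    """
    rng = np.random.default_rng(rng)
    if isinstance(design, SimulationDesign):
        design = design.realize(rng)
    data = design.sample(rng)
    return data, design.beta, design.S_star


# ---------------------------------------------------------------------------
# presets for the five reference studies

def example1() -> SimulationDesign:
    """Linear model, n=500, p=1000, s0=10, AR(1) rho=0.5, effects
    U[(-1.5,-0.5) u (0.5,1.5)]."""
    return SimulationDesign(
        n=500, p=1000, family="gaussian", corr="ar1", rho=0.5,
        coef_rule=("uniform_band", 0.5, 1.5, True),
        active_rule=("random", 10), intercept=0.0)


def example2() -> SimulationDesign:
    """Poisson model, n=300, p=400, s0=5, fixed effects 0.4..1.2 on a
    random active set."""
    return SimulationDesign(
        n=300, p=400, family="poisson", corr="identity",
        coef_rule=("fixed", (0.4, 0.6, 0.8, 1.0, 1.2)),
        active_rule=("random", 5), intercept=1.0)


def example3(corr: str = "identity", rho: float = 0.5) -> SimulationDesign:
    """Poisson model, n=400, p=500, s0=6, effects U[0.5, 1] (positive),
    identity / AR(1) rho=0.5 / CS rho=0.5."""
    return SimulationDesign(
        n=400, p=500, family="poisson", corr=corr,
        rho=rho if corr != "identity" else 0.0,
        coef_rule=("uniform_band", 0.5, 1.0, False),
        active_rule=("random", 6), intercept=1.0)


def example4(corr: str = "identity", rho: float = 0.5) -> SimulationDesign:
    """Logistic model, n=400, p=500, fixed S*={218,242,269,417} with
    effects (-2,-1,1,2)."""
    return SimulationDesign(
        n=400, p=500, family="binomial", corr=corr,
        rho=rho if corr != "identity" else 0.0,
        coef_rule=("fixed", (-2.0, -1.0, 1.0, 2.0)),
        active_rule=("fixed", (218, 242, 269, 417)), intercept=0.0)


def example5(rho: float = 0.25) -> SimulationDesign:
    """Logistic model, n=200, p=300, fixed S*={10,20,30} with effects
    (2,-2,2), AR(1) correlation."""
    return SimulationDesign(
        n=200, p=300, family="binomial", corr="ar1", rho=rho,
        coef_rule=("fixed", (2.0, -2.0, 2.0)),
        active_rule=("fixed", (10, 20, 30)), intercept=0.0)


PRESETS = {
    "example1": example1,
    "example2": example2,
    "example3": example3,
    "example4": example4,
    "example5": example5,
}


def get_preset(name: str, **kwargs) -> SimulationDesign:
    try:
        return PRESETS[name](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
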