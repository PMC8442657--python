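"""Linear exponential-family definitions for canonical-link GLMs.

The response density is ``f(y | theta) = exp{y*theta - A(theta) + c(y)}`` with
natural parameter ``theta`` equal to the linear predictor under the canonical
link.  Each family supplies the cumulant function ``A``, its derivatives
(mean ``A'`` and variance ``A''``), the canonical link ``g`` and its inverse,
and a response admissibility check.  ``c(y)`` never enters the optimisation
(it cancels in the average negative log-likelihood) and is not represented.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["Family", "GAUSSIAN", "BINOMIAL", "POISSON", "get_family"]

logger = logging.getLogger(__name__)

# Linear predictors are clamped to +-THETA_MAX inside exp() evaluations for the
# binomial and poisson families to avoid overflow; clamping events are logged.
THETA_MAX = 30.0


def _clamp(theta: np.ndarray, name: str) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) > THETA_MAX):
        logger.debug("clamping %s linear predictor to +-%.0f", name, THETA_MAX)
        theta = np.clip(theta, -THETA_MAX, THETA_MAX)
    return theta


class Family:
    """A canonical-link exponential family.

    Use the module-level singletons ``GAUSSIAN``, ``BINOMIAL``, ``POISSON``
    or :func:`get_family`.
    """

    name: str

    def cumulant(self, theta):
        """A(theta)."""
        raise NotImplementedError

    def mean(self, theta):
        """A'(theta), the inverse link applied to the linear predictor."""
        raise NotImplementedError

    def variance(self, mu):
        """nu(mu) = A''(theta) expressed through the mean."""
        raise NotImplementedError

    def link(self, mu):
        """Canonical link g(mu) = theta."""
        raise NotImplementedError

    def clamp_mean(self, mu):
        """Project a mean value into the (open) admissible mean space."""
        raise NotImplementedError

    def check_response(self, y: np.ndarray) -> None:
        """Raise ``ValueError`` naming the first offending index if ``y`` is
        not an admissible response for this family."""

    def __repr__(self) -> str:  # pragma: no cover
        return f"Family({self.name!r})"


class _Gaussian(Family):
    name = "gaussian"

    def cumulant(self, theta):
        theta = np.asarray(theta, dtype=float)
        return 0.5 * theta**2

    def mean(self, theta):
        return np.asarray(theta, dtype=float)

    def variance(self, mu):
        return np.ones_like(np.asarray(mu, dtype=float))

    def link(self, mu):
        return np.asarray(mu, dtype=float)

    def clamp_mean(self, mu):
        return np.asarray(mu, dtype=float)


class _Binomial(Family):
    name = "binomial"

    def cumulant(self, theta):
        theta = _clamp(theta, self.name)
        # log(1 + e^theta), computed stably
        return np.logaddexp(0.0, theta)

    def mean(self, theta):
        theta = _clamp(theta, self.name)
        return 1.0 / (1.0 + np.exp(-theta))

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu * (1.0 - mu)

    def link(self, mu):
        mu = np.asarray(mu, dtype=float)
        return np.log(mu / (1.0 - mu))

    def clamp_mean(self, mu):
        return np.clip(np.asarray(mu, dtype=float), 1e-10, 1.0 - 1e-10)

    def check_response(self, y: np.ndarray) -> None:
        bad = np.flatnonzero(~np.isin(y, (0.0, 1.0)))
        if bad.size:
            raise ValueError(
                f"binomial response must be 0/1; offending index {bad[0]}"
            )


class _Poisson(Family):
    name = "poisson"

    def cumulant(self, theta):
        theta = _clamp(theta, self.name)
        return np.exp(theta)

    def mean(self, theta):
        theta = _clamp(theta, self.name)
        return np.exp(theta)

    def variance(self, mu):
        return np.asarray(mu, dtype=float)

    def link(self, mu):
        return np.log(np.asarray(mu, dtype=float))

    def clamp_mean(self, mu):
        return np.maximum(np.asarray(mu, dtype=float), 1e-10)

    def check_response(self, y: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        bad = np.flatnonzero((y < 0) | (y != np.floor(y)))
        if bad.size:
            raise ValueError(
                "poisson response must be a non-negative integer; "
                f"offending index {bad[0]}"
            )


GAUSSIAN = _Gaussian()
BINOMIAL = _Binomial()
POISSON = _Poisson()

_FAMILIES = {f.name: f for f in (GAUSSIAN, BINOMIAL, POISSON)}


def get_family(name) -> Family:
    """Look up a family by name (``Family`` instances pass through)."""
    if isinstance(name, Family):
        return name
    try:
        return _FAMILIES[str(name).lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(_FAMILIES)}"
        ) from None
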