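import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_glm_data(rng, family, n, k, beta0=0.1, coef_scale=0.5):
    """Small random GLM instance with known generating coefficients."""
    X = rng.standard_normal((n, k))
    beta = coef_scale * rng.standard_normal(k)
    eta = beta0 + X @ beta
    if family == "gaussian":
        y = eta + rng.standard_normal(n)
    elif family == "binomial":
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    else:
        y = rng.poisson(np.exp(np.clip(eta, -20, 5))).astype(float)
    return X, y, np.r_[beta0, beta]
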