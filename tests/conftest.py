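import numpy as np
import pytest

from phycofit import LogisticParams, LuedekingPiretParams

# Published parameter regimes (k, alpha, beta) used throughout as
# round-trip ground truth.
CONDITIONS = {
    "C. salina N+": (0.4441, 0.125, 0.002),
    "C. salina N-": (0.3786, 0.164, 0.002),
    "N. oculata N+": (0.447, 0.151, 0.0006),
    "N. oculata N-": (0.4053, 0.211, 0.001),
}

X0, XS, P0 = 0.05, 2.0, 0.0


@pytest.fixture
def csalina_growth() -> LogisticParams:
    return LogisticParams(x0=X0, k=0.4441, xs=XS)


@pytest.fixture
def csalina_prod() -> LuedekingPiretParams:
    return LuedekingPiretParams(alpha=0.125, beta=0.002, p0=P0)


@pytest.fixture
def default_grid() -> np.ndarray:
    return np.linspace(0.0, 20.0, 30)


def random_param_sets(n: int, seed: int):
    """Random valid (growth, product) parameter pairs for property checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        xs = rng.uniform(0.5, 5.0)
        x0 = xs * rng.uniform(0.005, 0.5)
        k = rng.uniform(0.05, 1.0)
        alpha = rng.uniform(0.0, 0.5)
        beta = rng.uniform(0.0, 0.01)
        p0 = rng.uniform(0.0, 0.1)
        out.append(
            (
                LogisticParams(x0=x0, k=k, xs=xs),
                LuedekingPiretParams(alpha=alpha, beta=beta, p0=p0),
            )
        )
    return out
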