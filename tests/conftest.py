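import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def random_counts(rng):
    """A batch of small random 18-cell count tables."""
    def make(n=1, lo=0, hi=25):
        tables = rng.integers(lo, hi, size=(n, 3, 2, 3)).astype(float)
        return tables[0] if n == 1 else tables
    return make


@pytest.fixture()
def random_profile(rng):
    """Random case ancestry profiles (θ, N) with N ~ Binomial(2, θ)."""
    def make(m=30):
        theta = rng.uniform(0.05, 0.95, m)
        n_eur = rng.binomial(2, theta)
        return theta, n_eur
    return make
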