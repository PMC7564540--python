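import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epibalance import EpialleleMatrix, ModelParams

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def three_read_matrix():
    """Reads 000, 111, 101 over three CpG sites."""
    return EpialleleMatrix(sample_id="s1", n_sites=3, reads=["000", "111", "101"])


@pytest.fixture
def balanced_params():
    """No cooperativity, equal methylation and demethylation pressure."""
    return ModelParams(p=1.0, alpha=0.0, q=1.0, beta=0.0)


@pytest.fixture
def bimodal_params():
    """Strong symmetric cooperativity: bimodal stationary law at N = 9."""
    return ModelParams(p=0.05, alpha=0.1, q=0.05, beta=0.1)


@pytest.fixture
def recovery_params():
    """Ground truth with cooperativity ratios alpha/p = 4 and beta/q = 0.5."""
    return ModelParams(p=0.1, alpha=0.4, q=1.0 / 3.0, beta=1.0 / 6.0)


def random_params(rng: np.random.Generator) -> ModelParams:
    """A random valid parameter set on the unit simplex, away from absorbing
    boundaries (q + beta bounded below)."""
    while True:
        vals = rng.dirichlet(np.ones(4))
        if vals[2] + vals[3] > 0.05:
            return ModelParams(*vals)
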