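"""Shared fixtures.

The two trained networks are session-scoped because simulation-based
training is by far the most expensive step; every test that needs a trained
approximator shares the same checkpoint.
"""

import numpy as np
import pytest

from superstat.benchmarks import train_ddm_benchmark, train_poisson_benchmark


@pytest.fixture(scope="session")
def poisson_net():
    """Amortized filter trained on the Poisson + random-walk model."""
    return train_poisson_benchmark(seed=3)


@pytest.fixture(scope="session")
def ddm_net():
    """Amortized filter trained on the random-walk DDM."""
    return train_ddm_benchmark(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
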