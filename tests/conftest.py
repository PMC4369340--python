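import numpy as np
import pytest

import craniopgls as cp


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (16 taxa, study-like composition)."""
    return cp.simulate_study(cp.SimConfig(seed=2024))


@pytest.fixture(scope="session")
def tree16():
    return cp.simulate_tree(16, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_psd_covariance(n, rng):
    """PSD matrix from a random tree-free factor, for inv_sqrt/GLS tests."""
    A = rng.normal(size=(n, n + 3))
    return A @ A.T / (n + 3)
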