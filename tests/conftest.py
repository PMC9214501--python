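import numpy as np
import pytest

from ddcov import (
    LinearSimConfig,
    TimeSeries,
    motif_graph,
    simulate_linear,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def confounder():
    return motif_graph("confounder")


@pytest.fixture(scope="session")
def chain():
    return motif_graph("chain")


@pytest.fixture(scope="session")
def stable_w(rng):
    """A random 5-node stable coupling matrix (diagonally dominated decay)."""
    W = 0.3 * rng.standard_normal((5, 5))
    W -= np.eye(5) * (np.abs(W).sum(axis=1) + 0.5)
    assert np.max(np.linalg.eigvals(W).real) < 0
    return W


@pytest.fixture(scope="session")
def confounder_series(confounder):
    """Medium-length stochastic recording of the confounder motif."""
    return simulate_linear(LinearSimConfig(W=confounder.W, duration=200.0, seed=7))


@pytest.fixture()
def white_noise_series(rng):
    return TimeSeries(values=rng.standard_normal((4, 20000)), dt=0.01)
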