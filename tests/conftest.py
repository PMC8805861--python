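import numpy as np
import pytest

from dirconn.synthetic import fixture_networks, random_digraph


@pytest.fixture(scope="session")
def fixtures():
    return fixture_networks()


@pytest.fixture(scope="session")
def random_digraphs_10():
    """200 random 10-node digraphs spanning sparse to dense regimes."""
    graphs = []
    for s in range(200):
        p = 0.1 + 0.8 * (s % 10) / 9
        graphs.append(random_digraph(10, p, seed=s))
    return graphs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
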