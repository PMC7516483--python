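import pytest

from eminet import Network, toy_network


@pytest.fixture
def toy():
    """The 4-node directed weighted worked-example network."""
    return toy_network()


@pytest.fixture
def triangle():
    """Undirected unweighted K3."""
    net = Network(directed=False, weighted=False)
    net.add_edge("x", "y")
    net.add_edge("y", "z")
    net.add_edge("x", "z")
    return net
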