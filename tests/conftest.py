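import numpy as np
import pytest

from mpm.entities_io import DirectedInteractionNetwork, EntityRegistry, OntologyTree
from mpm.synthetic import SyntheticConfig, simulate_world


def make_network(edges, nodes=None):
    """Directed PCG network from a list of (source, target) id pairs."""
    reg = EntityRegistry("PCG")
    for n in nodes or []:
        reg.add(n)
    net = DirectedInteractionNetwork(reg)
    for s, t in edges:
        net.add_edge(s, t)
    return net


def make_tree(records):
    """OntologyTree from (node_id, code) pairs, closed over prefixes."""
    tree = OntologyTree()
    for node_id, code in records:
        tree.add(node_id, code)
    tree.close()
    return tree


def random_network(rng, n, mean_degree=3.0):
    """Random directed graph over n synthetic PCG ids."""
    ids = [f"G{i:03d}" for i in range(n)]
    net = make_network([], nodes=ids)
    for i in range(n):
        k = min(int(rng.poisson(mean_degree)), n - 1)
        for t in rng.choice(np.delete(np.arange(n), i), size=k, replace=False):
            net.add_edge(ids[i], ids[int(t)])
    return net


@pytest.fixture(scope="session")
def world():
    """One default synthetic world shared by read-only tests."""
    return simulate_world(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def dataset(world):
    return world.dataset
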