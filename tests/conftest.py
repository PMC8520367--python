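import numpy as np
import pytest

from tensorcut import FlowGraph


def random_spd(rng, scale=1.0, min_eig=0.05):
    """Random well-conditioned SPD 3x3 matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    eigs = rng.uniform(min_eig, 1.0, size=3) * scale
    return (q * eigs) @ q.T


def random_flow_graph(rng, n_nodes, integer=False, p_edge=0.5):
    """Random small s/t graph with mixed t-links and internal arcs."""
    g = FlowGraph()
    nodes = [f"n{k}" for k in range(n_nodes)]
    for node in nodes:
        g.add_node(node)
        if integer:
            g.add_t_links(node, float(rng.integers(0, 6)), float(rng.integers(0, 6)))
        else:
            g.add_t_links(node, float(rng.uniform(0, 5)), float(rng.uniform(0, 5)))
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < p_edge:
                c = float(rng.integers(0, 4)) if integer else float(rng.uniform(0, 3))
                g.add_n_link(nodes[a], nodes[b], c)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
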