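import random

import networkx as nx
import pytest

from lgclink import build_graph


@pytest.fixture
def p3():
    """Path a-b-c."""
    return build_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def k4():
    return build_graph(
        [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]]
    )


@pytest.fixture
def star4():
    """Center 'c' with leaves x, y, z."""
    return build_graph([("c", "x"), ("c", "y"), ("c", "z")])


def random_graph(n, p, seed):
    """ER graph with string labels, as the package produces them."""
    g = nx.erdos_renyi_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {v: str(v) for v in g})


@pytest.fixture
def random_graphs():
    return [random_graph(n, p, seed) for n, p, seed in
            [(20, 0.2, 1), (30, 0.15, 2), (30, 0.3, 3), (50, 0.1, 4), (15, 0.5, 5)]]


def shuffled_relabel(g, seed):
    """Random node-identifier permutation of g."""
    labels = list(g.nodes())
    shuffled = labels[:]
    random.Random(seed).shuffle(shuffled)
    mapping = dict(zip(labels, shuffled))
    return nx.relabel_nodes(g, mapping), mapping
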