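"""Synthetic graph generators and small analytic fixtures.

Random models (Erdős–Rényi, Barabási–Albert, Watts–Strogatz) stand in for
real networks so every index and metric is testable without downloads;
deterministic fixtures (complete, path, star, two disjoint triangles, and the
two small closeness-illustration graphs) carry exactly known closeness and
clustering values.

Barabási–Albert convention: networkx's, which starts from ``m_attach``
unconnected seed nodes and attaches each of the remaining ``n - m_attach``
nodes with ``m_attach`` edges, giving exactly ``m_attach * (n - m_attach)``
edges.  Generated node labels are decimal strings so generated graphs behave
identically to graphs read from edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .graph_core import Graph

__all__ = ["GenSpec", "generate", "fixture_figure1"]

_MODELS = (
    "erdos_renyi",
    "barabasi_albert",
    "watts_strogatz",
    "complete",
    "path",
    "star",
    "two_triangles",
)

_DETERMINISTIC = ("complete", "path", "star", "two_triangles")


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one synthetic graph.

    ``p`` is the ER edge probability or WS rewiring probability lives in
    ``p_rewire``; ``m_attach`` the BA attachment count; ``k_ring`` the even
    WS ring degree.  Deterministic fixtures ignore ``seed``.
    """

    model: str
    n: int
    p: Optional[float] = None
    m_attach: Optional[int] = None
    k_ring: Optional[int] = None
    p_rewire: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; valid: {', '.join(_MODELS)}"
            )
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.model == "erdos_renyi":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("erdos_renyi requires p in [0, 1]")
        if self.model == "barabasi_albert":
            if self.m_attach is None or not 1 <= self.m_attach < self.n:
                raise ValueError("barabasi_albert requires 1 <= m_attach < n")
        if self.model == "watts_strogatz":
            if self.k_ring is None or self.k_ring % 2 != 0 or self.k_ring >= self.n:
                raise ValueError("watts_strogatz requires even k_ring < n")
            if self.p_rewire is None or not 0.0 <= self.p_rewire <= 1.0:
                raise ValueError("watts_strogatz requires p_rewire in [0, 1]")
        if self.model == "two_triangles" and self.n != 6:
            raise ValueError("two_triangles is a fixed 6-node fixture (n=6)")


def _as_string_labels(g: nx.Graph) -> Graph:
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes()})


def generate(spec: GenSpec) -> Graph:
    """Build the graph a :class:`GenSpec` describes; seed-deterministic."""
    if spec.model == "complete":
        g = nx.complete_graph(spec.n)
    elif spec.model == "path":
        g = nx.path_graph(spec.n)
    elif spec.model == "star":
        g = nx.star_graph(spec.n - 1)  # center + n-1 leaves
    elif spec.model == "two_triangles":
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f")])
        return g
    elif spec.model == "erdos_renyi":
        g = nx.erdos_renyi_graph(spec.n, spec.p, seed=spec.seed)
    elif spec.model == "barabasi_albert":
        g = nx.barabasi_albert_graph(spec.n, spec.m_attach, seed=spec.seed)
    else:  # watts_strogatz
        g = nx.watts_strogatz_graph(spec.n, spec.k_ring, spec.p_rewire, seed=spec.seed)
    return _as_string_labels(g)


def fixture_figure1(variant: str) -> Graph:
    """The two small closeness-illustration graphs.

    Variant ``'a'``: the chain a–b–c (every clustering coefficient 0, the
    middle node closest to the rest).  Variant ``'b'``: the triangle a,b,c
    with a pendant edge a–d (positive clustering on the triangle, node a
    both well-clustered and close to everything).
    """
    if variant == "a":
        return nx.Graph([("a", "b"), ("b", "c")])
    if variant == "b":
        return nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
    raise ValueError(f"unknown variant {variant!r}; expected 'a' or 'b'")
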