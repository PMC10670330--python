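"""Graph container, edge-list I/O and the structural primitives the indices consume.

The graph type is :class:`networkx.Graph` restricted to undirected, unweighted
simple graphs: no self-loops, no parallel edges, every edge endpoint in the
node set.  Node identifiers are opaque hashables (plain strings when read from
an edge list); nothing here assumes integer labels.

Closeness centrality follows the classical definition
``C_v = (n - 1) / sum_j d(v, j)`` on connected graphs.  On disconnected graphs
the Wasserman–Faust component-scaled form is used,
``C_v = (r_v / (n - 1)) * (r_v / sum_{j reachable} d(v, j))`` with ``r_v`` the
number of other nodes ``v`` reaches; the two coincide when the graph is
connected and isolated nodes score 0.  This keeps every scorer total on the
training graphs produced by random edge removal, which are often disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx

__all__ = [
    "Graph",
    "GraphStats",
    "EdgeListError",
    "canonical_pair",
    "build_graph",
    "read_edgelist",
    "write_edgelist",
    "degree",
    "neighbors",
    "local_clustering",
    "shortest_path_lengths",
    "closeness",
    "all_closeness",
    "pair_closeness",
    "graph_stats",
]

Graph = nx.Graph


class EdgeListError(ValueError):
    """Malformed or invalid edge-list input."""


def canonical_pair(u, v) -> tuple:
    """Return the unordered pair (u, v) in canonical (string-sorted) order."""
    return (u, v) if str(u) <= str(v) else (v, u)


def build_graph(edges: Iterable[tuple], nodes: Iterable = ()) -> Graph:
    """Build a validated simple undirected graph from edges and extra nodes.

    Raises :class:`EdgeListError` on self-loops.  Duplicate edges (in either
    orientation) collapse to one.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            raise EdgeListError(f"self-loop on node {u!r} is not allowed")
        g.add_edge(u, v)
    return g


def _open_source(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_edgelist(source) -> Graph:
    """Parse a whitespace-delimited edge list from a path or text stream.

    Each non-blank line not starting with ``#`` must carry at least two
    tokens; the first two are the edge endpoints (kept as strings).  Duplicate
    lines and reversed duplicates collapse to a single undirected edge.

    Raises
    ------
    EdgeListError
        On a line with fewer than two tokens (naming the line number) or on a
        self-loop.
    """
    stream, close = _open_source(source)
    g = nx.Graph()
    try:
        for lineno, line in enumerate(stream, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListError(
                    f"line {lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                raise EdgeListError(f"line {lineno}: self-loop {u!r}-{v!r}")
            g.add_edge(u, v)
    finally:
        if close:
            stream.close()
    return g


def write_edgelist(g: Graph, sink) -> None:
    """Write one edge per line in deterministic canonical order.

    Endpoints are sorted within each pair and pairs are sorted
    lexicographically, so ``read_edgelist(write_edgelist(g))`` reproduces the
    edge set exactly.
    """
    lines = sorted(canonical_pair(u, v) for u, v in g.edges())
    text = "".join(f"{u} {v}\n" for u, v in lines)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def _require_node(g: Graph, v) -> None:
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")


def degree(g: Graph, v) -> int:
    _require_node(g, v)
    return g.degree(v)


def neighbors(g: Graph, v) -> set:
    _require_node(g, v)
    return set(g.neighbors(v))


def local_clustering(g: Graph, v) -> float:
    """Fraction of pairs of neighbors of ``v`` that are themselves linked.

    Zero (by convention) for nodes of degree < 2.
    """
    _require_node(g, v)
    return nx.clustering(g, v)


def shortest_path_lengths(g: Graph, source) -> dict:
    """BFS hop distances from ``source``; unreachable nodes are absent."""
    _require_node(g, source)
    return dict(nx.single_source_shortest_path_length(g, source))


def closeness(g: Graph, v) -> float:
    """Component-scaled closeness centrality of ``v`` (see module docstring)."""
    _require_node(g, v)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    dist = nx.single_source_shortest_path_length(g, v)
    total = sum(dist.values())
    reachable = len(dist) - 1
    if reachable == 0 or total == 0:
        return 0.0
    return (reachable / (n - 1)) * (reachable / total)


def all_closeness(g: Graph) -> dict:
    """Closeness of every node, one BFS per node."""
    return {v: closeness(g, v) for v in g.nodes()}


def pair_closeness(g: Graph, u, v) -> float:
    """Node-pair closeness: the sum of the two endpoint closeness values."""
    if u == v:
        raise ValueError(f"pair closeness is undefined for identical nodes ({u!r})")
    return closeness(g, u) + closeness(g, v)


@dataclass(frozen=True)
class GraphStats:
    """Cached network-level quantities reused by the scorers.

    ``avg_shortest_path`` is the mean hop distance over unordered *reachable*
    pairs only (0 when fewer than two nodes are mutually reachable);
    ``avg_clustering`` is the mean of the local clustering coefficient over
    all nodes.  ``closeness`` and ``clustering`` are per-node caches so the
    LGC-family scorers never recompute a BFS per candidate pair.
    """

    n: int
    m: int
    density: float
    avg_clustering: float
    avg_shortest_path: float
    closeness: Mapping = field(repr=False)
    clustering: Mapping = field(repr=False)

    def pair_closeness(self, u, v) -> float:
        if u == v:
            raise ValueError("pair closeness is undefined for identical nodes")
        return self.closeness[u] + self.closeness[v]


def graph_stats(g: Graph) -> GraphStats:
    """Compute n, m, density, average clustering and average shortest path.

    Raises ``ValueError`` on an empty (zero-node) graph.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("graph_stats requires a non-empty graph")
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    clustering = nx.clustering(g)
    avg_clustering = sum(clustering.values()) / n

    # mean distance over ordered reachable pairs == mean over unordered pairs
    total = 0
    pairs = 0
    for v in g.nodes():
        dist = nx.single_source_shortest_path_length(g, v)
        total += sum(dist.values())
        pairs += len(dist) - 1
    avg_sp = total / pairs if pairs > 0 else 0.0

    return GraphStats(
        n=n,
        m=m,
        density=density,
        avg_clustering=avg_clustering,
        avg_shortest_path=avg_sp,
        closeness=all_closeness(g),
        clustering=clustering,
    )
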