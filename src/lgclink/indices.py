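"""Similarity indices for link prediction.

Twelve scorers share one calling convention: the classical local baselines
CN, AA, RA, PA, CCLP and CN2D; the path-based Katz and local-path (LP)
indices; and the closeness-based family — the local term LC, the global term
GC, and their λ-weighted combinations LGC and LGC*.

The LGC score of a candidate pair (x, y) is

    S_xy = λ · Σ_{z ∈ Γx ∩ Γy} (C_{x,y} + CC_z) / k_z  +  (1 − λ) · GC_{x,y}

where C_{x,y} = C_x + C_y is the pair closeness, CC_z the local clustering
coefficient and k_z the degree of the common neighbor z, and the global term
combines pair closeness with the network-average clustering coefficient CC
and average shortest path length d.  LGC* squares the per-neighbor numerator,
(C_{x,y} + CC_z)², which widens the gap between strong and weak candidates.

All network-level statistics are computed on the graph handed in — during
evaluation that is the training graph, so probe information never leaks into
a score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .graph_core import Graph, GraphStats, canonical_pair, graph_stats

__all__ = [
    "INDEX_NAMES",
    "IndexParams",
    "ScoreTable",
    "candidate_pairs",
    "cn_score",
    "aa_score",
    "ra_score",
    "pa_score",
    "cclp_score",
    "cn2d_score",
    "katz_score",
    "lp_score",
    "lc_score",
    "gc_score",
    "lgc_score",
    "lgc_star_score",
    "score_index",
]

INDEX_NAMES = (
    "cn",
    "katz",
    "pa",
    "aa",
    "ra",
    "cn2d",
    "lp",
    "cclp",
    "lc",
    "gc",
    "lgc",
    "lgc_star",
)


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters shared by the scorers.

    lambda_weight : λ ∈ [0, 1], weight of the local term in LGC/LGC*
        (default 0.8, the empirically best balance).
    katz_beta : path-damping factor of the Katz index; must stay strictly
        below 1/ρ(A) (checked at scoring time against the adjacency spectral
        radius).
    lp_epsilon : weight of the 3-walk term in the local-path index
        A² + ε·A³.
    cn2d_beta : weight of the degree-normalized second-order term in CN2D.
    gc_form : reading of the global closeness term — ``"product"``
        (C_{x,y} · CC / d, default; defined even when CC = 0) or
        ``"inverse"`` (C_{x,y} / (d · CC)).
    dense_cap : maximum node count for the dense-matrix Katz/LP solvers.
    """

    lambda_weight: float = 0.8
    katz_beta: float = 0.01
    lp_epsilon: float = 0.001
    cn2d_beta: float = 0.1
    gc_form: str = "product"
    dense_cap: int = 3000

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError(
                f"lambda_weight must be in [0, 1], got {self.lambda_weight}"
            )
        if self.katz_beta < 0:
            raise ValueError(f"katz_beta must be >= 0, got {self.katz_beta}")
        if self.lp_epsilon < 0:
            raise ValueError(f"lp_epsilon must be >= 0, got {self.lp_epsilon}")
        if self.cn2d_beta < 0:
            raise ValueError(f"cn2d_beta must be >= 0, got {self.cn2d_beta}")
        if self.gc_form not in ("product", "inverse"):
            raise ValueError(
                f"gc_form must be 'product' or 'inverse', got {self.gc_form!r}"
            )

    def with_lambda(self, lam: float) -> "IndexParams":
        return replace(self, lambda_weight=lam)


class ScoreTable:
    """Map from unordered candidate node pair to a real similarity score.

    Keys are canonicalized so ``table[(u, v)]`` and ``table[(v, u)]`` agree;
    :meth:`get` defaults to 0.0 for pairs the scorer never touched, which
    keeps the ranked universe identical across indices.
    """

    def __init__(self, scores: Optional[dict] = None):
        self._scores: dict = {}
        if scores:
            for (u, v), s in scores.items():
                self.set(u, v, s)

    def set(self, u, v, score: float) -> None:
        if u == v:
            raise ValueError("a score table never pairs a node with itself")
        self._scores[canonical_pair(u, v)] = float(score)

    def get(self, u, v, default: float = 0.0) -> float:
        return self._scores.get(canonical_pair(u, v), default)

    def __getitem__(self, pair) -> float:
        return self._scores[canonical_pair(*pair)]

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def __iter__(self):
        return iter(self._scores)

    def items(self):
        return self._scores.items()

    def ranked(self) -> list:
        """Pairs sorted by descending score, ties broken by canonical order."""
        return sorted(self._scores, key=lambda p: (-self._scores[p], p))

    def write_tsv(self, sink) -> None:
        lines = ["node_u\tnode_v\tscore\n"]
        for u, v in self.ranked():
            lines.append(f"{u}\t{v}\t{self._scores[(u, v)]:.10g}\n")
        text = "".join(lines)
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text, encoding="utf-8")
        else:
            sink.write(text)


def candidate_pairs(g: Graph) -> set:
    """All unordered pairs of distinct nodes not joined by an edge."""
    if g.number_of_nodes() == 0:
        raise ValueError("candidate_pairs requires a non-empty graph")
    pairs = set()
    for u, v in combinations(g.nodes(), 2):
        if not g.has_edge(u, v):
            pairs.add(canonical_pair(u, v))
    return pairs


def _common_neighbors(g: Graph, u, v) -> set:
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return set(g[u]) & set(g[v])


def cn_score(g: Graph, u, v) -> int:
    """Common-neighbor count |Γu ∩ Γv|."""
    return len(_common_neighbors(g, u, v))


def aa_score(g: Graph, u, v) -> float:
    """Adamic–Adar: Σ 1/ln(k_z) over common neighbors (k_z ≥ 2 always)."""
    return sum(1.0 / math.log(g.degree(z)) for z in _common_neighbors(g, u, v))


def ra_score(g: Graph, u, v) -> float:
    """Resource allocation: Σ 1/k_z over common neighbors."""
    return sum(1.0 / g.degree(z) for z in _common_neighbors(g, u, v))


def pa_score(g: Graph, u, v) -> int:
    """Preferential attachment: k_u · k_v."""
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return g.degree(u) * g.degree(v)


def cclp_score(g: Graph, u, v) -> float:
    """Sum of the local clustering coefficient over common neighbors."""
    cns = _common_neighbors(g, u, v)
    if not cns:
        return 0.0
    cc = nx.clustering(g, cns)
    return sum(cc.values())


def cn2d_score(g: Graph, u, v, params: Optional[IndexParams] = None) -> float:
    """CN plus a degree-normalized second-order term:
    |Γu∩Γv| + β · (1/max(k_u, k_v)) · Σ_z |Γz|."""
    params = params or IndexParams()
    cns = _common_neighbors(g, u, v)
    base = len(cns)
    if not cns:
        return 0.0
    kmax = max(g.degree(u), g.degree(v))
    second = sum(g.degree(z) for z in cns)
    return base + params.cn2d_beta * second / kmax


def _adjacency(g: Graph, params: IndexParams):
    n = g.number_of_nodes()
    if n > params.dense_cap:
        raise ValueError(
            f"dense matrix solver limited to {params.dense_cap} nodes "
            f"(graph has {n}); raise IndexParams.dense_cap if memory allows"
        )
    order = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=order, dtype=float)
    return order, a


def _table_from_matrix(order, s, pairs) -> ScoreTable:
    idx = {v: i for i, v in enumerate(order)}
    table = ScoreTable()
    for u, v in pairs:
        table.set(u, v, s[idx[u], idx[v]])
    return table


def katz_score(
    g: Graph, params: Optional[IndexParams] = None, pairs: Optional[Iterable] = None
) -> ScoreTable:
    """Katz index S = (I − βA)⁻¹ − I over the candidate pairs.

    Requires β < 1/ρ(A); otherwise raises ``ValueError`` naming the bound.
    """
    params = params or IndexParams()
    order, a = _adjacency(g, params)
    # adjacency of an undirected graph is symmetric -> real spectrum
    rho = float(np.max(np.abs(np.linalg.eigvalsh(a)))) if len(order) else 0.0
    if rho > 0 and params.katz_beta >= 1.0 / rho:
        raise ValueError(
            f"katz_beta={params.katz_beta} must be < 1/spectral_radius = {1.0 / rho:.6g}"
        )
    n = len(order)
    s = np.linalg.inv(np.eye(n) - params.katz_beta * a) - np.eye(n)
    if pairs is None:
        pairs = candidate_pairs(g)
    return _table_from_matrix(order, s, pairs)


def lp_score(
    g: Graph, params: Optional[IndexParams] = None, pairs: Optional[Iterable] = None
) -> ScoreTable:
    """Local-path index S = A² + ε·A³ over the candidate pairs."""
    params = params or IndexParams()
    order, a = _adjacency(g, params)
    a2 = a @ a
    s = a2 + params.lp_epsilon * (a2 @ a)
    if pairs is None:
        pairs = candidate_pairs(g)
    return _table_from_matrix(order, s, pairs)


def lc_score(g: Graph, u, v, stats: Optional[GraphStats] = None) -> float:
    """Local attribute closeness: Σ_z (C_{u,v} + CC_z) / k_z over common
    neighbors; 0 when there are none."""
    stats = stats if stats is not None else graph_stats(g)
    cns = _common_neighbors(g, u, v)
    if not cns:
        return 0.0
    c_uv = stats.pair_closeness(u, v)
    return sum((c_uv + stats.clustering[z]) / g.degree(z) for z in cns)


def gc_score(
    g: Graph,
    u,
    v,
    stats: Optional[GraphStats] = None,
    params: Optional[IndexParams] = None,
) -> float:
    """Global attribute closeness built from pair closeness, the network
    average clustering CC and the average shortest path length d."""
    stats = stats if stats is not None else graph_stats(g)
    params = params or IndexParams()
    c_uv = stats.pair_closeness(u, v)
    d = stats.avg_shortest_path
    cc = stats.avg_clustering
    if d <= 0:
        raise ValueError("global closeness requires avg_shortest_path > 0")
    if params.gc_form == "product":
        return c_uv * cc / d
    if cc == 0:
        raise ValueError(
            "gc_form='inverse' is undefined on a network with zero average clustering"
        )
    return c_uv / (d * cc)


def lgc_score(
    g: Graph,
    u,
    v,
    stats: Optional[GraphStats] = None,
    params: Optional[IndexParams] = None,
) -> float:
    """λ-weighted combination of the local and global closeness terms."""
    stats = stats if stats is not None else graph_stats(g)
    params = params or IndexParams()
    lam = params.lambda_weight
    return lam * lc_score(g, u, v, stats) + (1.0 - lam) * gc_score(
        g, u, v, stats, params
    )


def lgc_star_score(
    g: Graph,
    u,
    v,
    stats: Optional[GraphStats] = None,
    params: Optional[IndexParams] = None,
) -> float:
    """LGC with the per-neighbor local numerator squared: (C_{u,v} + CC_z)²."""
    stats = stats if stats is not None else graph_stats(g)
    params = params or IndexParams()
    lam = params.lambda_weight
    cns = _common_neighbors(g, u, v)
    local = 0.0
    if cns:
        c_uv = stats.pair_closeness(u, v)
        local = sum(
            (c_uv + stats.clustering[z]) ** 2 / g.degree(z) for z in cns
        )
    return lam * local + (1.0 - lam) * gc_score(g, u, v, stats, params)


def score_index(
    g: Graph,
    index_name: str,
    params: Optional[IndexParams] = None,
    pairs: Optional[Iterable] = None,
) -> ScoreTable:
    """Score every candidate pair (or the given pairs) under one index.

    Network-level statistics are computed once per call, never per pair.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(
            f"unknown index {index_name!r}; valid names: {', '.join(INDEX_NAMES)}"
        )
    params = params or IndexParams()
    if pairs is None:
        pairs = candidate_pairs(g)
    pairs = [canonical_pair(u, v) for u, v in pairs]

    if index_name == "katz":
        return katz_score(g, params, pairs)
    if index_name == "lp":
        return lp_score(g, params, pairs)

    table = ScoreTable()
    adj = {v: set(g[v]) for v in g.nodes()}
    deg = dict(g.degree())

    if index_name in ("cn", "pa"):
        for u, v in pairs:
            if index_name == "cn":
                table.set(u, v, len(adj[u] & adj[v]))
            else:
                table.set(u, v, deg[u] * deg[v])
        return table

    if index_name in ("aa", "ra", "cclp", "cn2d"):
        cc = nx.clustering(g) if index_name == "cclp" else None
        for u, v in pairs:
            cns = adj[u] & adj[v]
            if index_name == "aa":
                s = sum(1.0 / math.log(deg[z]) for z in cns)
            elif index_name == "ra":
                s = sum(1.0 / deg[z] for z in cns)
            elif index_name == "cclp":
                s = sum(cc[z] for z in cns)
            else:  # cn2d
                s = 0.0
                if cns:
                    kmax = max(deg[u], deg[v])
                    s = len(cns) + params.cn2d_beta * sum(deg[z] for z in cns) / kmax
            table.set(u, v, s)
        return table

    # closeness-based family: stats computed once
    stats = graph_stats(g)
    d = stats.avg_shortest_path
    cc_avg = stats.avg_clustering
    if index_name in ("gc", "lgc", "lgc_star") and d <= 0:
        raise ValueError("global closeness requires avg_shortest_path > 0")
    if index_name in ("gc", "lgc", "lgc_star") and params.gc_form == "inverse" and cc_avg == 0:
        raise ValueError(
            "gc_form='inverse' is undefined on a network with zero average clustering"
        )
    lam = params.lambda_weight
    clo = stats.closeness
    clu = stats.clustering
    for u, v in pairs:
        c_uv = clo[u] + clo[v]
        if index_name == "lc":
            s = sum((c_uv + clu[z]) / deg[z] for z in adj[u] & adj[v])
        else:
            if params.gc_form == "product":
                gc = c_uv * cc_avg / d
            else:
                gc = c_uv / (d * cc_avg)
            if index_name == "gc":
                s = gc
            elif index_name == "lgc":
                local = sum((c_uv + clu[z]) / deg[z] for z in adj[u] & adj[v])
                s = lam * local + (1.0 - lam) * gc
            else:  # lgc_star
                local = sum((c_uv + clu[z]) ** 2 / deg[z] for z in adj[u] & adj[v])
                s = lam * local + (1.0 - lam) * gc
        table.set(u, v, s)
    return table
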