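"""Edge-holdout evaluation: splits, AUC, precision@m and the trial harness.

The protocol removes a random fraction of edges (the probe set E_P, positives)
and scores the remaining training graph.  AUC is the probability that a probe
pair outscores a non-edge of the original graph (ties count half):

    AUC = (N1 + 0.5 N2) / N3

computed either exhaustively over all probe x non-edge comparisons or by
seeded sampling.  Precision@m is the fraction of probe edges among the m
top-scored candidate pairs.  Every quantity here is a pure function of
(graph, parameters, master seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .graph_core import Graph, canonical_pair
from .indices import IndexParams, ScoreTable, score_index

__all__ = [
    "SplitResult",
    "EvalResult",
    "derive_seed",
    "split_edges",
    "auc",
    "precision_at",
    "run_experiment",
    "lambda_sweep",
    "ratio_sweep",
]


@dataclass(frozen=True)
class SplitResult:
    """Partition of the edge set into a training graph and probe edges."""

    train: Graph
    probe_edges: frozenset
    ratio: float
    seed: int


@dataclass(frozen=True)
class EvalResult:
    """Per-trial and aggregated AUC/precision for one configuration."""

    index_name: str
    ratio: float
    reps: int
    auc_values: tuple
    precision_values: tuple
    params: IndexParams

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def precision_mean(self) -> float:
        return float(np.mean(self.precision_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": range(1, self.reps + 1),
                "auc": self.auc_values,
                "precision": self.precision_values,
            }
        )


def derive_seed(master: int, trial: int) -> int:
    """Mix (master seed, trial index) into an independent sub-seed < 2^31.

    Splitmix64-style finalizer, so consecutive trials are decorrelated yet
    fully reproducible from the master seed.
    """
    z = (master * 0x9E3779B97F4A7C15 + trial + 1) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


def split_edges(g: Graph, ratio: float, seed: int) -> SplitResult:
    """Randomly hold out round((1-ratio)·m) edges as the probe set.

    The training graph keeps the full node set (nodes are never removed, even
    if they end up isolated).  Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    m = g.number_of_edges()
    if m < 2:
        raise ValueError(f"need at least 2 edges to split, got {m}")
    n_train = round(ratio * m)
    n_probe = m - n_train
    if n_probe == 0 or n_train == 0:
        raise ValueError(
            f"ratio {ratio} with m={m} leaves an empty training or probe set"
        )
    edges = sorted(canonical_pair(u, v) for u, v in g.edges())
    rng = random.Random(seed)
    probe = frozenset(rng.sample(edges, n_probe))
    train = g.__class__()
    train.add_nodes_from(g.nodes())
    train.add_edges_from(e for e in edges if e not in probe)
    return SplitResult(train=train, probe_edges=probe, ratio=ratio, seed=seed)


def _scores_array(scores: ScoreTable, pairs: Iterable) -> np.ndarray:
    return np.array([scores.get(u, v) for u, v in pairs], dtype=float)


def auc(
    scores: ScoreTable,
    probe_edges: Iterable,
    non_edges: Iterable,
    mode: str = "auto",
    n_samples: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 1_000_000,
) -> float:
    """AUC = (N1 + 0.5·N2)/N3 over probe (positive) vs non-edge (negative)
    score comparisons.

    ``mode='exhaustive'`` counts all |probe|·|non_edges| ordered comparisons
    (vectorized via a sorted negative array, so large products stay cheap);
    ``'sampled'`` draws ``n_samples`` independent positive/negative pairs with
    a seeded RNG; ``'auto'`` picks exhaustive when the comparison count is at
    most ``exhaustive_limit``.  Pairs missing from the table score 0.
    """
    pos_pairs = list(probe_edges)
    neg_pairs = list(non_edges)
    if not pos_pairs or not neg_pairs:
        raise ValueError("AUC needs non-empty positive and negative sets")
    if mode not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown AUC mode {mode!r}")
    pos = _scores_array(scores, pos_pairs)
    neg = _scores_array(scores, neg_pairs)
    if mode == "auto":
        mode = "exhaustive" if pos.size * neg.size <= exhaustive_limit else "sampled"
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        p = pos[rng.integers(0, pos.size, n_samples)]
        q = neg[rng.integers(0, neg.size, n_samples)]
        n1 = int(np.sum(p > q))
        n2 = int(np.sum(p == q))
        return (n1 + 0.5 * n2) / n_samples
    neg_sorted = np.sort(neg)
    below = np.searchsorted(neg_sorted, pos, side="left")  # negatives < pos
    upto = np.searchsorted(neg_sorted, pos, side="right")  # negatives <= pos
    n1 = int(below.sum())
    n2 = int((upto - below).sum())
    n3 = pos.size * neg.size
    return (n1 + 0.5 * n2) / n3


def precision_at(scores: ScoreTable, probe_edges: Iterable, m: int) -> float:
    """Fraction of probe edges among the m top-scored candidate pairs.

    Ranking is by descending score with canonical pair order breaking ties
    deterministically.  ``m`` may not exceed the number of scored pairs.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m > len(scores):
        raise ValueError(
            f"m={m} exceeds the {len(scores)} scored candidate pairs"
        )
    probe = {canonical_pair(u, v) for u, v in probe_edges}
    top = scores.ranked()[:m]
    hits = sum(1 for pair in top if pair in probe)
    return hits / m


def _resolve_m(m: Union[int, str], n_probe: int) -> int:
    if m == "probe":
        return n_probe
    return int(m)


def run_experiment(
    g: Graph,
    index_name: str,
    params: Optional[IndexParams] = None,
    ratio: float = 0.9,
    reps: int = 50,
    m: Union[int, str] = 100,
    auc_mode: str = "auto",
    seed: int = 42,
    auc_samples: int = 10_000,
) -> EvalResult:
    """Repeated random-split evaluation of one index.

    Trial t splits with the sub-seed derived from (seed, t), scores the
    training graph's candidate pairs using training information only, and
    evaluates AUC (probe vs original-graph non-edges) and precision@m.
    ``m='probe'`` uses each trial's probe-set size.
    """
    params = params or IndexParams()
    non_edges = frozenset(
        canonical_pair(u, v)
        for u, v in combinations(g.nodes(), 2)
        if not g.has_edge(u, v)
    )
    if not non_edges:
        raise ValueError("graph is complete; no negative pairs to rank against")
    aucs, precs = [], []
    for t in range(reps):
        sub = derive_seed(seed, t)
        split = split_edges(g, ratio, sub)
        if not split.probe_edges:
            raise ValueError("empty probe set in trial")
        candidates = set(non_edges) | set(split.probe_edges)
        scores = score_index(split.train, index_name, params, pairs=candidates)
        aucs.append(
            auc(
                scores,
                split.probe_edges,
                non_edges,
                mode=auc_mode,
                n_samples=auc_samples,
                seed=sub,
            )
        )
        precs.append(
            precision_at(scores, split.probe_edges, _resolve_m(m, len(split.probe_edges)))
        )
    return EvalResult(
        index_name=index_name,
        ratio=ratio,
        reps=reps,
        auc_values=tuple(aucs),
        precision_values=tuple(precs),
        params=params,
    )


def lambda_sweep(
    g: Graph,
    index_name: str,
    lambdas: Sequence[float],
    ratio: float = 0.9,
    reps: int = 50,
    m: Union[int, str] = 100,
    seed: int = 42,
    params: Optional[IndexParams] = None,
    auc_mode: str = "auto",
) -> pd.DataFrame:
    """Evaluate LGC or LGC* over a grid of λ values.

    The same master seed (hence identical splits) is shared across λ values,
    so row-to-row differences are attributable to λ alone.
    """
    if index_name not in ("lgc", "lgc_star"):
        raise ValueError("lambda_sweep applies to 'lgc' or 'lgc_star' only")
    params = params or IndexParams()
    rows = []
    for lam in lambdas:
        res = run_experiment(
            g,
            index_name,
            params.with_lambda(lam),
            ratio=ratio,
            reps=reps,
            m=m,
            auc_mode=auc_mode,
            seed=seed,
        )
        rows.append(
            {"lambda": lam, "auc_mean": res.auc_mean, "precision_mean": res.precision_mean}
        )
    return pd.DataFrame(rows)


def ratio_sweep(
    g: Graph,
    index_name: str,
    params: Optional[IndexParams] = None,
    ratios: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 50,
    m: Union[int, str] = 100,
    seed: int = 42,
    auc_mode: str = "auto",
) -> pd.DataFrame:
    """Training-ratio robustness sweep (default grid 50%..90%)."""
    rows = []
    for ratio in ratios:
        res = run_experiment(
            g, index_name, params, ratio=ratio, reps=reps, m=m,
            auc_mode=auc_mode, seed=seed,
        )
        rows.append(
            {"ratio": ratio, "auc_mean": res.auc_mean, "precision_mean": res.precision_mean}
        )
    return pd.DataFrame(rows)
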