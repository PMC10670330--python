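# Methods

## Problem and model

Given an undirected, unweighted simple graph `G(V, E)`, link prediction
assigns each unconnected node pair a similarity score `S_xy`; pairs ranked
higher are taken to be more likely missing or future links. The package's
core index family combines two signals:

- a **local term**: for each common neighbor `z` of the pair, the pair
  closeness `C_{x,y} = C_x + C_y` plus the local clustering coefficient
  `CC_z`, divided by the degree `k_z` (so well-connected intermediaries
  contribute less per link, as in resource-allocation style indices);
- a **global term**: the pair closeness scaled by the network-average
  clustering coefficient `CC` and average shortest path length `d`.

LGC is the convex combination `λ·local + (1−λ)·global`; LGC* squares the
per-neighbor numerator `(C_{x,y}+CC_z)²` in the local term, amplifying
already-high proximity values and demoting low ones. The underlying
assumption is that of all neighborhood-based predictors: edges form
preferentially between pairs that are locally embedded (shared, tightly
clustered neighbors) and globally central.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `lambda_weight` | weight of the local term, dimensionless ∈ [0,1] | 0.8 | the empirically best balance; `λ=1` reduces to the LC component, `λ=0` to GC |
| `katz_beta` | Katz path damping | 0.01 | must be `< 1/ρ(A)`; validated at scoring time against the adjacency spectral radius |
| `lp_epsilon` | weight of the 3-walk term in `A²+εA³` | 0.001 | `ε=0` reduces to 2-walk counts (= CN on triangle-free graphs) |
| `cn2d_beta` | weight of CN2D's degree-normalized second-order term | 0.1 | `β=0` reduces to CN |
| `gc_form` | reading of the global term | `product` | see below |
| split `ratio` | training fraction of edges | 0.9 | probe size is `m − round(ratio·m)` |
| `reps` | random splits per evaluation | 50 | means of per-trial AUC/precision are reported |
| precision `m` | ranking cutoff | 100 | `"probe"` uses each trial's probe-set size; required on graphs with fewer than 100 candidate pairs |

## Design choices where the design was open

- **Global-term form.** The linearized definition of the global closeness is
  ambiguous between `C_{x,y}·CC/d` and `C_{x,y}/(d·CC)`. The product form is
  the default: it encodes that both higher network clustering and shorter
  average paths raise link likelihood, and it remains defined on
  triangle-free networks where `CC = 0` (the inverse form is available as
  `gc_form="inverse"` and raises a clear error in that degenerate case).
- **LGC\* squaring.** The square is applied to the whole per-neighbor
  numerator `(C_{x,y}+CC_z)²` rather than to `CC_z` alone; this is the
  reading under which the analytic value on K4 (`LGC*(λ=0.8) = 5.2`) holds
  and the one that sharpens the full proximity signal, not only the
  clustering part.
- **Disconnected training graphs.** Random edge removal frequently
  disconnects the graph, so closeness uses the Wasserman–Faust
  component-scaled form `(r_v/(n−1))·(r_v/Σd)`, which coincides with the
  classical `(n−1)/Σd` on connected graphs; isolated nodes score 0. The
  average shortest path length is the mean over mutually reachable pairs
  only, and local clustering of degree-<2 nodes is 0. None of these
  conventions affect the connected, simple-graph case.
- **Negatives for AUC.** Negative pairs are the non-edges of the *original*
  graph (pairs in neither the training nor the probe set); positives are the
  probe edges. Scoring sees only the training graph, so no probe information
  leaks into any statistic — closeness, clustering averages and path lengths
  are all recomputed per trial on the training graph.
- **Unscored pairs score 0** rather than being dropped, so every index ranks
  the identical candidate universe.
- **Tie-breaking.** Top-`m` ranking orders by descending score, then
  canonical (lexicographic) pair order. This makes precision deterministic
  for tie-heavy scorers such as CN on sparse graphs; users should expect the
  tie-break, not chance, to resolve those ranks.
- **Per-trial seeds** derive from `(master_seed, trial_index)` through a
  splitmix64-style finalizer, keeping trials decorrelated yet bit-
  reproducible; derived seeds stay below 2³¹.

## Numerical notes

- Exhaustive AUC counts all `|probe|·|non-edges|` comparisons exactly but is
  evaluated with a sorted-array/`searchsorted` formulation, so large
  comparison counts cost `O((P+N)·log N)`, not `O(P·N)`. It equals the
  Mann–Whitney U statistic normalized by the comparison count (verified
  against `scipy.stats.mannwhitneyu` in the tests). Auto mode switches to
  seeded sampling (10 000 draws) above 10⁶ comparisons.
- Katz and LP use dense matrix algebra (`numpy.linalg.inv`, matrix
  products); they are limited to `dense_cap` (default 3000) nodes, and the
  Katz β is validated against the spectral radius computed by a symmetric
  eigensolver.
- Splits take `round(ratio·m)` training edges and the remainder as probe,
  sampling from the canonically ordered edge list with a `random.Random`
  instance, so split composition is independent of hash ordering.

## What the synthetic generators emulate — and what they do not

Erdős–Rényi, Barabási–Albert (networkx convention: `m_attach·(n−m_attach)`
edges from unconnected seed nodes) and Watts–Strogatz graphs stand in for
real networks so every index and metric is exercised without downloads;
small analytic fixtures (complete graphs, paths, stars, two disjoint
triangles, a chain and a triangle-with-pendant) carry exactly known
closeness and clustering values. Synthetic models reproduce heavy-tailed
degrees (BA) and high clustering with short paths (WS), but not the degree–
clustering correlations, community structure or core–periphery organization
of real interaction networks. Passing tests therefore demonstrate
correctness of the computations and sensible ranking behaviour on graphs
with known structure — not that any index achieves a particular accuracy on
a particular real dataset.

Benchmark problem sizes used in the test suite and the acceptance script —
a 200-node Watts–Strogatz graph (ring degree 6, rewiring 0.1, 20
repetitions) and the 34-node karate-club network (50 repetitions) — were
chosen as the smallest configurations on which the AUC separation between
index families is stable across seeds.

## Known limitations

- Dense Katz/LP restrict those two indices to moderate graphs; the other
  ten indices scale with the candidate-pair count.
- Scoring all `O(n²)` candidate pairs is quadratic by construction; no
  candidate pruning (e.g. distance-2 restriction) is applied, so rankings
  remain comparable across indices.
- Only undirected, unweighted simple graphs are supported — no multigraphs,
  weights, directions or temporal dynamics.
- Precision@m on small graphs is dominated by the tie-break when scores
  collapse to few distinct values; use `m="probe"` and compare indices under
  the identical protocol rather than reading absolute values.
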