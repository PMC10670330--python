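"""Similarity indices: hand values, brute-force oracles, reductions."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from lgclink import IndexParams, candidate_pairs, graph_stats
from lgclink.indices import (
    INDEX_NAMES,
    aa_score,
    cclp_score,
    cn2d_score,
    cn_score,
    gc_score,
    katz_score,
    lc_score,
    lgc_score,
    lgc_star_score,
    lp_score,
    pa_score,
    ra_score,
    score_index,
)

from .conftest import random_graph, shuffled_relabel


class TestCandidatePairs:
    def test_complete_graph_empty(self, k4):
        assert candidate_pairs(k4) == set()

    def test_path(self, p3):
        assert candidate_pairs(p3) == {("a", "c")}

    def test_empty_graph_all_pairs(self):
        g = nx.empty_graph(6)
        assert len(candidate_pairs(g)) == 15


class TestLocalBaselines:
    """Hand-evaluated values on K4 and the path a-b-c."""

    def test_cn(self, k4, p3):
        assert cn_score(k4, "a", "b") == 2
        assert cn_score(p3, "a", "c") == 1

    def test_cn_across_components(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        assert cn_score(g, "a", "x") == 0

    def test_aa(self, k4, p3):
        assert aa_score(k4, "a", "b") == pytest.approx(2 / math.log(3), abs=1e-12)
        assert aa_score(p3, "a", "c") == pytest.approx(1 / math.log(2), abs=1e-12)
        assert aa_score(p3, "a", "b") == 0.0

    def test_ra(self, k4, p3):
        assert ra_score(k4, "a", "b") == pytest.approx(2 / 3, abs=1e-12)
        assert ra_score(p3, "a", "c") == pytest.approx(0.5, abs=1e-12)

    def test_pa(self, k4, star4):
        assert pa_score(k4, "a", "b") == 9
        assert pa_score(star4, "x", "y") == 1

    def test_pa_isolated(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        assert pa_score(g, "z", "a") == 0

    def test_cclp(self, k4, p3):
        assert cclp_score(k4, "a", "b") == pytest.approx(2.0, abs=1e-12)
        assert cclp_score(p3, "a", "c") == 0.0

    def test_cn2d(self, k4):
        # 2 common neighbors of degree 3 each: 2 + 0.1*(1/3)*6 = 2.2
        assert cn2d_score(k4, "a", "b") == pytest.approx(2.2, abs=1e-12)

    def test_cn2d_beta_zero_reduces_to_cn(self):
        g = random_graph(25, 0.2, seed=8)
        params = IndexParams(cn2d_beta=0.0)
        for u, v in list(candidate_pairs(g))[:30]:
            assert cn2d_score(g, u, v, params) == cn_score(g, u, v)

    def test_unknown_node_raises(self, p3):
        for fn in (cn_score, aa_score, ra_score, pa_score, cclp_score):
            with pytest.raises(KeyError):
                fn(p3, "a", "zz")

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_oracle(self, seed):
        """CN/AA/RA/CCLP match naive set-intersection implementations."""
        g = random_graph(25, 0.2, seed=seed)
        for u, v in list(combinations(g.nodes(), 2))[::3]:
            cns = {z for z in g.nodes()
                   if g.has_edge(u, z) and g.has_edge(v, z)}
            assert cn_score(g, u, v) == len(cns)
            assert aa_score(g, u, v) == pytest.approx(
                sum(1 / math.log(g.degree(z)) for z in cns))
            assert ra_score(g, u, v) == pytest.approx(
                sum(1 / g.degree(z) for z in cns))
            assert cclp_score(g, u, v) == pytest.approx(
                sum(nx.clustering(g, z) for z in cns))


def _power_series_katz(g, beta, terms=20):
    order = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=order)
    s = np.zeros_like(a)
    ak = np.eye(len(order))
    for k in range(1, terms + 1):
        ak = ak @ a
        s += beta**k * ak
    return order, s


class TestMatrixIndices:
    def test_katz_matches_power_series(self):
        for seed in range(3):
            g = random_graph(25, 0.15, seed=seed)
            a = nx.to_numpy_array(g)
            rho = max(abs(np.linalg.eigvalsh(a)))
            beta = 0.1 / rho
            table = katz_score(g, IndexParams(katz_beta=beta))
            order, s = _power_series_katz(g, beta)
            idx = {v: i for i, v in enumerate(order)}
            for u, v in table:
                assert table.get(u, v) == pytest.approx(
                    s[idx[u], idx[v]], abs=1e-9)

    def test_katz_beta_zero_all_zero(self):
        g = random_graph(15, 0.3, seed=1)
        table = katz_score(g, IndexParams(katz_beta=0.0))
        assert all(s == 0.0 for _, s in table.items())

    def test_katz_beta_above_spectral_bound_rejected(self, k4):
        # rho(K4) = 3, so beta must be < 1/3
        with pytest.raises(ValueError, match="spectral"):
            katz_score(k4, IndexParams(katz_beta=0.5))

    def test_lp_path(self, p3):
        table = lp_score(p3)
        assert table.get("a", "c") == pytest.approx(1.0)

    def test_lp_matches_walk_counts(self):
        g = random_graph(20, 0.2, seed=4)
        eps = 0.001
        a = nx.to_numpy_array(g)
        order = list(g.nodes())
        idx = {v: i for i, v in enumerate(order)}
        expect = a @ a + eps * (a @ a @ a)
        table = lp_score(g, IndexParams(lp_epsilon=eps))
        for u, v in table:
            assert table.get(u, v) == pytest.approx(expect[idx[u], idx[v]])

    def test_lp_epsilon_zero_equals_cn_on_triangle_free(self):
        tree = nx.relabel_nodes(nx.random_labeled_tree(20, seed=9), str)
        table = lp_score(tree, IndexParams(lp_epsilon=0.0))
        for u, v in table:
            assert table.get(u, v) == cn_score(tree, u, v)


class TestClosenessFamily:
    def test_lc_hand_values(self, k4, p3, star4):
        assert lc_score(k4, "a", "b") == pytest.approx(2.0, abs=1e-12)
        assert lc_score(p3, "a", "c") == pytest.approx(2 / 3, abs=1e-12)
        assert lc_score(star4, "x", "y") == pytest.approx(0.4, abs=1e-12)

    def test_lc_no_common_neighbors(self, p3):
        assert lc_score(p3, "a", "b") == 0.0

    def test_gc_hand_values(self, k4, p3):
        assert gc_score(k4, "a", "b") == pytest.approx(2.0, abs=1e-12)
        assert gc_score(p3, "a", "c") == 0.0  # CC = 0 in product form

    def test_gc_forms_coincide_on_k4(self, k4):
        prod = gc_score(k4, "a", "b", params=IndexParams(gc_form="product"))
        inv = gc_score(k4, "a", "b", params=IndexParams(gc_form="inverse"))
        assert prod == inv == 2.0

    def test_gc_inverse_degenerate_on_zero_clustering(self, p3):
        with pytest.raises(ValueError, match="clustering"):
            gc_score(p3, "a", "c", params=IndexParams(gc_form="inverse"))

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.8, 1.0])
    def test_lgc_k4_constant_in_lambda(self, k4, lam):
        assert lgc_score(k4, "a", "b", params=IndexParams(lambda_weight=lam)) \
            == pytest.approx(2.0, abs=1e-12)

    def test_lgc_path_hand_value(self, p3):
        assert lgc_score(p3, "a", "c") == pytest.approx(0.8 * 2 / 3, abs=1e-12)

    def test_lgc_star_k4(self, k4):
        # local = 2*(3^2/3) = 6; 0.8*6 + 0.2*2 = 5.2
        assert lgc_star_score(k4, "a", "b") == pytest.approx(5.2, abs=1e-12)

    def test_endpoint_reductions(self):
        for seed in range(3):
            g = random_graph(20, 0.25, seed=seed)
            stats = graph_stats(g)
            for u, v in list(candidate_pairs(g))[:20]:
                assert lgc_score(g, u, v, stats, IndexParams(lambda_weight=1.0)) \
                    == pytest.approx(lc_score(g, u, v, stats))
                assert lgc_score(g, u, v, stats, IndexParams(lambda_weight=0.0)) \
                    == pytest.approx(gc_score(g, u, v, stats))
                assert lgc_star_score(g, u, v, stats, IndexParams(lambda_weight=0.0)) \
                    == pytest.approx(gc_score(g, u, v, stats))

    def test_lgc_star_dominates_when_numerators_exceed_one(self, k4):
        # on K4 every (C + CC_z) = 3 >= 1, so the squared local term dominates
        lam = IndexParams(lambda_weight=1.0)
        assert lgc_star_score(k4, "a", "b", params=lam) >= \
            lgc_score(k4, "a", "b", params=lam)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            IndexParams(lambda_weight=1.5)


class TestScoreIndex:
    def test_dispatch_path_cn(self, p3):
        table = score_index(p3, "cn")
        assert dict(table.items()) == {("a", "c"): 1.0}

    def test_complete_graph_empty_table(self, k4):
        assert len(score_index(k4, "lgc")) == 0

    def test_unknown_index_rejected(self, p3):
        with pytest.raises(ValueError, match="valid names"):
            score_index(p3, "jaccard")

    @pytest.mark.parametrize("name", INDEX_NAMES)
    def test_table_matches_per_pair_functions(self, name):
        """The vectorized dispatcher agrees with the single-pair scorers."""
        g = random_graph(18, 0.25, seed=6)
        params = IndexParams()
        stats = graph_stats(g)
        table = score_index(g, name, params)
        per_pair = {
            "cn": lambda u, v: cn_score(g, u, v),
            "aa": lambda u, v: aa_score(g, u, v),
            "ra": lambda u, v: ra_score(g, u, v),
            "pa": lambda u, v: pa_score(g, u, v),
            "cclp": lambda u, v: cclp_score(g, u, v),
            "cn2d": lambda u, v: cn2d_score(g, u, v, params),
            "lc": lambda u, v: lc_score(g, u, v, stats),
            "gc": lambda u, v: gc_score(g, u, v, stats, params),
            "lgc": lambda u, v: lgc_score(g, u, v, stats, params),
            "lgc_star": lambda u, v: lgc_star_score(g, u, v, stats, params),
        }
        if name in per_pair:
            for u, v in list(table)[::5]:
                assert table.get(u, v) == pytest.approx(per_pair[name](u, v))
        else:
            assert len(table) == len(candidate_pairs(g))

    @pytest.mark.parametrize("name", INDEX_NAMES)
    def test_symmetry_and_nonnegativity(self, name):
        g = random_graph(15, 0.3, seed=2)
        table = score_index(g, name)
        for u, v in table:
            s = table.get(u, v)
            assert s == table.get(v, u)
            assert np.isfinite(s) and s >= 0

    @pytest.mark.parametrize("name", INDEX_NAMES)
    def test_relabeling_invariance(self, name):
        g = random_graph(14, 0.3, seed=10)
        h, mapping = shuffled_relabel(g, seed=77)
        tg = score_index(g, name)
        th = score_index(h, name)
        for u, v in tg:
            assert tg.get(u, v) == pytest.approx(th.get(mapping[u], mapping[v]))


class TestScoreTable:
    def test_symmetric_keys(self, p3):
        table = score_index(p3, "cn")
        assert table.get("c", "a") == table.get("a", "c") == 1.0

    def test_unscored_pairs_default_zero(self, p3):
        table = score_index(p3, "cn")
        assert table.get("a", "b") == 0.0

    def test_tsv_output_sorted_by_descending_score(self, tmp_path):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
        table = score_index(g, "cn")
        out = tmp_path / "scores.tsv"
        table.write_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "node_u\tnode_v\tscore"
        scores = [float(line.split("\t")[2]) for line in lines[1:]]
        assert scores == sorted(scores, reverse=True)
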