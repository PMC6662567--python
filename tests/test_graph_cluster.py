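"""Capped-degree graph, Fisher's-method membership, deterministic LPA."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from tetrabin.graph_cluster import (
    BinningParams,
    Labeling,
    SparseGraph,
    build_seed_graph,
    fisher_combined_p,
    fisher_membership,
    iterative_partition,
    lpa_round,
)


def chi2_sf_oracle(x, df):
    """Independent chi-square upper tail: numerical integration of the
    density (no scipy.stats involved)."""

    def pdf(t):
        return math.exp(
            (df / 2 - 1) * math.log(t) - t / 2 - gammaln(df / 2) - (df / 2) * math.log(2)
        )

    if x <= 0:
        return 1.0
    val, _ = quad(pdf, x, max(x + 40 * math.sqrt(2 * df), 200), limit=300)
    return val


class TestTopkInsert:
    def test_retains_top_two_of_three_offers(self):
        g = SparseGraph(["u", "a", "b", "c"], k=2)
        for v, s in [("a", 0.5), ("b", 0.9), ("c", 0.7)]:
            g.topk_insert("u", v, s)
        assert set(g.retained("u")) == {"b", "c"}

    def test_tie_keeps_lexicographically_smaller_neighbor(self):
        g = SparseGraph(["u", "a", "b"], k=1)
        g.topk_insert("u", "b", 0.8)
        g.topk_insert("u", "a", 0.8)
        assert set(g.retained("u")) == {"a"}

    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = 50
            k = int(rng.integers(1, 8))
            nodes = [f"n{i:02d}" for i in range(n)]
            g = SparseGraph(nodes, k=k)
            iu, ju = np.triu_indices(n, 1)
            scores = rng.random(len(iu))
            order = rng.permutation(len(iu))
            dense = np.full((n, n), -1.0)
            for idx in order:
                i, j = int(iu[idx]), int(ju[idx])
                g.topk_insert(nodes[i], nodes[j], float(scores[idx]))
                dense[i, j] = dense[j, i] = scores[idx]
            for i in range(n):
                offered = [(dense[i, j], nodes[j]) for j in range(n) if dense[i, j] >= 0]
                # best-k by score desc, then neighbor id asc
                expect = sorted(offered, key=lambda t: (-t[0], t[1]))[:k]
                assert g.retained(nodes[i]) == {v: s for s, v in expect}
                assert len(g.neighbors(nodes[i])) <= k

    def test_self_loops_rejected(self):
        g = SparseGraph(["a", "b"], k=2)
        with pytest.raises(ValueError):
            g.topk_insert("a", "a", 0.5)

    def test_active_edges_are_mutual(self):
        # b's cap evicts the (a,b) edge, so it must vanish from a's active
        # adjacency even though a still has room
        g = SparseGraph(["a", "b", "c", "d"], k=1)
        g.topk_insert("a", "b", 0.5)
        g.topk_insert("b", "c", 0.9)
        assert g.neighbors("a") == {}
        assert g.neighbors("b") == {"c": 0.9}


class TestFisherMembership:
    def test_zero_score_single_candidate(self):
        # 1 - S = 1, X = 0, combined p = 1: weakest evidence, still chosen
        assert fisher_combined_p([0.0]) == pytest.approx(1.0)
        assert fisher_membership({"A": [0.0]}) == "A"

    def test_two_strong_edges_beat_one(self):
        # X = -2*2*ln(0.05) ~ 11.98 (df 4) vs single 0.95 (p = 0.05)
        p_a = fisher_combined_p([0.95, 0.95])
        p_b = fisher_combined_p([0.95])
        assert p_a == pytest.approx(0.0175, abs=2e-3)
        assert p_b == pytest.approx(0.05, abs=1e-9)
        assert fisher_membership({"A": [0.95, 0.95], "B": [0.95]}) == "A"

    def test_neighborhood_size_tradeoff_decided_by_combined_p(self):
        scores = {"A": [0.5] * 10, "B": [0.99]}
        p_a = chi2_sf_oracle(-2 * 10 * math.log(0.5), 20)
        p_b = chi2_sf_oracle(-2 * math.log(0.01), 2)
        expect = "A" if p_a < p_b else "B"
        assert fisher_membership(scores) == expect

    def test_agrees_with_integration_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            s = rng.random(m) * 0.999
            p = fisher_combined_p(s)
            x = -2 * np.sum(np.log1p(-s))
            ref = chi2_sf_oracle(float(x), 2 * m)
            if ref > 1e-300:
                worst = max(worst, abs(p - ref) / ref)
        assert worst < 1e-9

    def test_score_one_is_floored_not_infinite(self):
        p = fisher_combined_p([1.0])
        assert 0.0 <= p < 1e-10

    def test_tie_prefers_current_label_else_lexicographic(self):
        scores = {"B": [0.7], "A": [0.7]}
        assert fisher_membership(scores, current_label="B") == "B"
        assert fisher_membership(scores, current_label="Z") == "A"
        assert fisher_membership(scores) == "A"


def two_triangle_graph():
    nodes = list("abcdef")
    g = SparseGraph(nodes, k=5)
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.topk_insert(u, v, 0.9)
    for u, v in [("d", "e"), ("e", "f"), ("d", "f")]:
        g.topk_insert(u, v, 0.8)
    return g


class TestLpaRound:
    def test_single_edge_pair_shares_label(self):
        g = SparseGraph(["u", "v"], k=2)
        g.topk_insert("u", "v", 0.9)
        lab = lpa_round(g, Labeling.singletons(["u", "v"]))
        assert lab.label["u"] == lab.label["v"]

    def test_disconnected_triangles_keep_two_labels(self):
        g = two_triangle_graph()
        lab = Labeling.singletons(list("abcdef"))
        for _ in range(5):
            lab = lpa_round(g, lab)
        labels = set(lab.label.values())
        assert len(labels) == 2
        assert len({lab.label[n] for n in "abc"}) == 1
        assert len({lab.label[n] for n in "def"}) == 1

    def test_deterministic(self):
        g1, g2 = two_triangle_graph(), two_triangle_graph()
        l1 = lpa_round(g1, Labeling.singletons(list("abcdef")))
        l2 = lpa_round(g2, Labeling.singletons(list("abcdef")))
        assert l1.label == l2.label

    def test_isolated_node_keeps_label(self):
        g = SparseGraph(["a", "b", "z"], k=2)
        g.topk_insert("a", "b", 0.5)
        lab = lpa_round(g, Labeling.singletons(["a", "b", "z"]))
        assert lab.label["z"] == "z"


def planted_cliques(n_cliques=3, size=3, s_in=0.9, s_out=0.1):
    nodes = [f"c{q}n{i}" for q in range(n_cliques) for i in range(size)]
    edges = []
    for q in range(n_cliques):
        members = [f"c{q}n{i}" for i in range(size)]
        for a in range(size):
            for b in range(a + 1, size):
                edges.append((s_in, members[a], members[b]))
    for q in range(n_cliques - 1):
        edges.append((s_out, f"c{q}n0", f"c{q + 1}n0"))
    return nodes, edges


class TestIterativePartition:
    def test_planted_cliques_recovered(self):
        nodes, edges = planted_cliques()
        params = BinningParams(min_s=60.0, max_edges=10)
        graph = SparseGraph(nodes, params.max_edges)
        lab = iterative_partition(nodes, graph, edges, params, s_start=0.9)
        groups = {}
        for n, l in lab.label.items():
            groups.setdefault(l, set()).add(n)
        assert len(groups) == 3
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"c{q}n{i}" for i in range(3)) for q in range(3)
        }

    def test_label_count_non_increasing_in_admitted_edges(self):
        nodes, edges = planted_cliques(n_cliques=4, size=4, s_in=0.9, s_out=0.7)
        counts = []
        for min_s in (99.0, 80.0, 50.0, 1.0):
            params = BinningParams(min_s=min_s, max_edges=10)
            graph = SparseGraph(nodes, params.max_edges)
            cand = [e for e in edges if e[0] >= min_s / 100]
            lab = iterative_partition(nodes, graph, cand, params, s_start=0.95)
            counts.append(len(set(lab.label.values())))
        assert counts == sorted(counts, reverse=True)

    def test_warm_start_matches_cold_fixed_point(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i:02d}" for i in range(24)]
        edges = []
        for i in range(24):
            for j in range(i + 1, 24):
                if rng.random() < 0.3:
                    # communities of 8 via block structure
                    same = i // 8 == j // 8
                    edges.append((0.85 if same else 0.3, nodes[i], nodes[j]))
        params = BinningParams(min_s=20.0, max_edges=30, schedule_steps=6)
        g1 = SparseGraph(nodes, params.max_edges)
        warm = iterative_partition(nodes, g1, edges, params, s_start=0.85)
        # cold: admit everything at once, then propagate to a fixed point
        params_cold = BinningParams(min_s=20.0, max_edges=30, schedule_steps=1)
        g2 = SparseGraph(nodes, params_cold.max_edges)
        cold = iterative_partition(nodes, g2, edges, params_cold, s_start=0.2)
        def parts(lab):
            groups = {}
            for n, l in lab.label.items():
                groups.setdefault(l, set()).add(n)
            return {frozenset(s) for s in groups.values()}
        assert parts(warm) == parts(cold)

    def test_no_edges_leaves_singletons(self):
        params = BinningParams()
        nodes = ["a", "b"]
        lab = iterative_partition(nodes, SparseGraph(nodes, 5), [], params)
        assert lab.label == {"a": "a", "b": "b"}

    def test_deterministic_end_to_end(self):
        nodes, edges = planted_cliques(4, 5, 0.9, 0.5)
        runs = []
        for _ in range(2):
            params = BinningParams(min_s=40.0, max_edges=8)
            graph = SparseGraph(nodes, params.max_edges)
            runs.append(iterative_partition(nodes, graph, list(edges), params, 0.9).label)
        assert runs[0] == runs[1]


class TestBuildSeedGraph:
    def test_cutoff_and_cap(self):
        nodes = ["a", "b", "c"]
        tnf = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        weights = np.full((3, 3), 0.7)
        params = BinningParams(max_edges=1)
        g = build_seed_graph(nodes, tnf, weights, cutoff=0.5, params=params)
        assert g.neighbors("a") == {"b": 0.7}
        assert g.neighbors("c") == {}

    def test_empty_universe(self):
        g = build_seed_graph([], np.zeros((0, 0)), np.zeros((0, 0)), 0.5, BinningParams())
        assert g.nodes == []


class TestBinningParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(max_p=0), dict(max_p=101), dict(min_s=100), dict(max_edges=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BinningParams(**kwargs)
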