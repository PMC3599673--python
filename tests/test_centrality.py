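import itertools
import random

import networkx as nx
import numpy as np
import pytest

from condl.centrality import (
    betweenness_centrality,
    closeness_centrality,
    compare_top_sets,
    compute_report,
    degree_centrality,
    eigenvector_centrality,
    top_k,
)


def _graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes, ntype="gene")
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n].setdefault("ntype", "gene")
    return g


def brute_betweenness(g: nx.Graph) -> dict:
    """All-shortest-paths enumeration: for every unordered pair, the fraction
    of shortest paths passing through each interior node."""
    out = {n: 0.0 for n in g.nodes}
    nodes = sorted(g.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            out[n] += through / len(paths)
    return out


def dense_eigenvector(g: nx.Graph) -> dict:
    """Dominant eigenvector from a full symmetric eigendecomposition."""
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(adj)
    vec = v[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return dict(zip(nodes, vec))


class TestDegree:
    def test_star(self):
        s = degree_centrality(_graph([("c", "a"), ("c", "b"), ("c", "d")]))
        assert s == {"c": 3, "a": 1, "b": 1, "d": 1}

    def test_isolated_node(self):
        assert degree_centrality(_graph([], nodes=["x"]))["x"] == 0

    def test_triangle_symmetric(self):
        s = degree_centrality(_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert set(s.values()) == {2}

    def test_adding_edge_never_decreases(self):
        g = _graph([("a", "b"), ("b", "c")])
        before = degree_centrality(g)
        g.add_edge("a", "c")
        after = degree_centrality(g)
        assert all(after[n] >= before[n] for n in before)


class TestEigenvector:
    def test_triangle_uniform(self):
        s = eigenvector_centrality(_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        for v in s.values():
            assert v == pytest.approx(1 / np.sqrt(3), abs=1e-8)

    def test_path_middle_dominates(self):
        s = eigenvector_centrality(_graph([("a", "m"), ("m", "b")]))
        assert s["m"] > s["a"] and s["m"] > s["b"]

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(_graph([], nodes=["x", "y"]))

    def test_nonconvergence_reports_gap(self):
        with pytest.raises(ValueError, match="gap"):
            eigenvector_centrality(_graph([("a", "m"), ("m", "b")]), max_iter=1)

    def test_matches_dense_oracle_on_random_connected_graphs(self):
        rng = random.Random(8)
        trials = 0
        while trials < 100:
            n = rng.randint(2, 8)
            g = nx.gnp_random_graph(n, 0.5, seed=rng.randint(0, 10**6))
            if not nx.is_connected(g):
                continue
            trials += 1
            ours = eigenvector_centrality(g)
            oracle = dense_eigenvector(g)
            for node in g.nodes:
                assert abs(ours[node] - oracle[node]) < 1e-8


class TestCloseness:
    def test_p3_middle_is_one(self):
        s = closeness_centrality(_graph([("a", "m"), ("m", "b")]))
        assert s["m"] == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        s = closeness_centrality(_graph([("a", "b")], nodes=["x"]))
        assert s["x"] == 0.0

    def test_component_correction(self):
        # K2 plus isolated node, N = 3: each K2 node scores (1/1)*(1/2)
        s = closeness_centrality(_graph([("a", "b")], nodes=["x"]))
        assert s["a"] == pytest.approx(0.5)
        assert s["b"] == pytest.approx(0.5)


class TestBetweenness:
    def test_p3(self):
        s = betweenness_centrality(_graph([("a", "m"), ("m", "b")]))
        assert s == {"a": 0.0, "m": 1.0, "b": 0.0}

    def test_star_center_counts_pairs(self):
        s = betweenness_centrality(
            _graph([("c", "a"), ("c", "b"), ("c", "d"), ("c", "e")])
        )
        assert s["c"] == 6.0  # C(4, 2)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = random.Random(9)
        for _ in range(100):
            n = rng.randint(2, 8)
            g = nx.gnp_random_graph(n, 0.4, seed=rng.randint(0, 10**6))
            ours = betweenness_centrality(g)
            oracle = brute_betweenness(g)
            for node in g.nodes:
                assert ours[node] == pytest.approx(oracle[node], abs=1e-9)


class TestRelabelInvariance:
    def test_all_metrics_respect_isomorphism(self):
        rng = random.Random(10)
        g = nx.gnp_random_graph(7, 0.5, seed=11)
        while g.number_of_edges() == 0:
            g = nx.gnp_random_graph(7, 0.5, seed=rng.randint(0, 100))
        mapping = {n: f"node_{n}" for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        for fn in (
            degree_centrality,
            eigenvector_centrality,
            closeness_centrality,
            betweenness_centrality,
        ):
            sg, sh = fn(g), fn(h)
            for n in g.nodes:
                assert sg[n] == pytest.approx(sh[mapping[n]], abs=1e-8)


class TestRankingAndComparison:
    def test_top_k_truncates_to_available_nodes(self):
        report = compute_report(_graph([("a", "b"), ("b", "c")]))
        assert len(top_k(report, "degree", 10)) == 3

    def test_tie_at_boundary_prefers_smaller_id(self):
        # triangle: all scores tie; ordering is id-ascending
        report = compute_report(_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert top_k(report, "degree", 1) == ["a"]

    def test_competition_ranks_share_on_ties(self):
        report = compute_report(_graph([("c", "a"), ("c", "b"), ("c", "d")]))
        assert report.ranks["degree"]["c"] == 1
        assert {report.ranks["degree"][n] for n in "abd"} == {2}

    def test_k1_on_star_selects_center(self):
        report = compute_report(_graph([("c", "a"), ("c", "b"), ("c", "d")]))
        assert top_k(report, "betweenness", 1) == ["c"]

    def test_identical_networks_have_no_exclusive_genes(self):
        g = _graph([("a", "b"), ("b", "c")])
        report = compute_report(g)
        cmp = compare_top_sets(report, report, 2)
        assert cmp.a_only == cmp.b_only == frozenset()

    def test_disjoint_networks_share_nothing(self):
        ra = compute_report(_graph([("a", "b")]))
        rb = compute_report(_graph([("x", "y")]))
        assert compare_top_sets(ra, rb, 2).both == frozenset()

    def test_hand_ranked_fixture_groups(self):
        """Network A is the path G1-G2-G3-G4-G5; network B a star around G5.
        With k = 1: in A, degree ties at 2 resolve to G2 (id order) while
        eigenvector/closeness/betweenness all pick the middle node G3, so
        top-any(A) = {G2, G3}; in B every measure picks the hub G5.  G3
        reaches the top only through non-degree measures in A and never in
        B, so it lands in a_only."""
        a = _graph([("G1", "G2"), ("G2", "G3"), ("G3", "G4"), ("G4", "G5")])
        b = _graph([("G5", "G6"), ("G5", "G7"), ("G5", "G8")])
        cmp = compare_top_sets(compute_report(a), compute_report(b), 1)
        assert cmp.both == frozenset()
        assert cmp.a_only == frozenset({"G2", "G3"})
        assert cmp.b_only == frozenset({"G5"})

    def test_vaccine_nodes_excluded_from_ranking(self):
        g = nx.Graph()
        g.add_node("IL6", ntype="gene")
        g.add_node("VO:1", ntype="vaccine")
        g.add_edge("IL6", "VO:1")
        report = compute_report(g)
        assert report.nodes == ["IL6"]
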