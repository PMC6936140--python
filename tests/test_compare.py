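"""Topology metrics vs brute-force oracles, edge similarity, alignment."""

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from stagenet.compare import (
    align,
    degree_histogram,
    edge_similarity,
    metrics,
    metrics_table,
    stage_specific_subnetworks,
)


def graph(edges, nodes=None, kinds=None):
    g = nx.Graph()
    for n in nodes or []:
        g.add_node(n)
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n]["kind"] = (kinds or {}).get(n, "gene")
    return g


def naive_betweenness(g):
    """Path-counting oracle: enumerate all shortest paths per pair."""
    out = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


class TestEdgeSimilarity:
    def test_identical_networks(self):
        g = graph([("a", "b"), ("b", "c")])
        assert edge_similarity(g, g) == 1.0

    def test_disjoint_edge_sets(self):
        assert edge_similarity(graph([("a", "b")]), graph([("c", "d")])) == 0.0

    def test_partial_overlap_jaccard(self):
        a = graph([("a", "b"), ("b", "c")])
        b = graph([("a", "b"), ("c", "d")])
        assert edge_similarity(a, b) == pytest.approx(1 / 3)

    def test_first_denominator_is_asymmetric(self):
        a = graph([("a", "b"), ("b", "c")])
        b = graph([("a", "b")])
        assert edge_similarity(a, b, denominator="first") == pytest.approx(0.5)
        assert edge_similarity(b, a, denominator="first") == pytest.approx(1.0)

    def test_symmetric_under_jaccard(self):
        a = graph([("a", "b"), ("b", "c")])
        b = graph([("a", "b"), ("c", "d")])
        assert edge_similarity(a, b) == edge_similarity(b, a)

    def test_both_empty_defined_as_one(self):
        assert edge_similarity(nx.Graph(), nx.Graph()) == 1.0


class TestMetrics:
    def test_path_graph_p3(self):
        m = metrics(graph([("a", "b"), ("b", "c")]))
        assert m.diameter == 2
        # closeness = [1/3, 1/2, 1/3], betweenness = [0, 1, 0]
        assert m.mean_closeness == pytest.approx((1 / 3 + 1 / 2 + 1 / 3) / 3)
        assert m.mean_betweenness == pytest.approx(1 / 3)

    def test_star_center_betweenness(self):
        g = nx.star_graph(4)
        bet = nx.betweenness_centrality(g, normalized=False)
        assert bet[0] == pytest.approx(6.0)  # C(4,2) pairs through the hub
        m = metrics(g)
        assert m.mean_betweenness == pytest.approx(6.0 / 5)
        assert m.diameter == 2

    def test_complete_k4(self):
        m = metrics(nx.complete_graph(4))
        assert m.edge_density == 1.0
        assert m.diameter == 1
        assert m.mean_betweenness == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            metrics(nx.Graph())

    def test_isolated_node_zero_closeness_counts_component(self):
        g = graph([("a", "b")], nodes=["c"])
        m = metrics(g)
        assert m.n_components == 2
        assert m.mean_closeness == pytest.approx((1 + 1) / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracles_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        m = metrics(g)
        # diameter / closeness via Floyd-Warshall
        d = floyd_warshall(nx.to_numpy_array(g, weight=None), directed=False, unweighted=True)
        finite = np.where(np.isfinite(d), d, 0.0)
        assert m.diameter == int(finite.max())
        closeness = [1.0 / finite[i].sum() if finite[i].sum() else 0.0 for i in range(len(d))]
        assert m.mean_closeness == pytest.approx(np.mean(closeness), abs=1e-12)
        # betweenness via explicit path enumeration
        bet = naive_betweenness(g)
        assert m.mean_betweenness == pytest.approx(np.mean(list(bet.values())), abs=1e-9)


class TestDegreeHistogram:
    def test_k4(self):
        assert degree_histogram(nx.complete_graph(4)) == {3: 4}

    def test_star(self):
        assert degree_histogram(nx.star_graph(4)) == {4: 1, 1: 4}

    def test_handshake(self):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        hist = degree_histogram(g)
        assert sum(d * c for d, c in hist.items()) == 2 * g.number_of_edges()
        assert sum(hist.values()) == g.number_of_nodes()


class TestAlign:
    def test_self_alignment_is_identity_with_2m_objective(self):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        res = align(g, g, anchor_labels=True, seed=0)
        assert all(k == v for k, v in res.correspondence.items())
        assert res.objective == 2 * g.number_of_edges()

    def test_recovers_planted_isomorphism(self):
        recovered = []
        for seed in range(5):
            a = nx.gnp_random_graph(30, 0.2, seed=seed)
            perm = np.random.default_rng(seed).permutation(30)
            b = nx.relabel_nodes(a, {i: f"b{int(perm[i])}" for i in a.nodes})
            a2 = nx.relabel_nodes(a, {i: f"a{i}" for i in a.nodes})
            res = align(a2, b, anchor_labels=False, seed=seed)
            good = sum(res.correspondence.get(f"a{i}") == f"b{int(perm[i])}" for i in range(30))
            recovered.append(good / 30)
        assert np.mean(recovered) >= 0.9

    def test_objective_beats_random_permutation_baseline(self):
        rng = np.random.default_rng(2)
        a = nx.gnp_random_graph(25, 0.25, seed=2)
        b = a.copy()
        b.remove_edges_from(list(b.edges())[:: 10])  # delete ~10% of edges
        a = nx.relabel_nodes(a, {i: f"x{i}" for i in a.nodes})
        b = nx.relabel_nodes(b, {i: f"y{i}" for i in b.nodes})
        res = align(a, b, anchor_labels=False, seed=0)
        A = nx.to_numpy_array(a, nodelist=sorted(a.nodes))
        B = nx.to_numpy_array(b, nodelist=sorted(b.nodes))
        baselines = []
        for _ in range(100):
            p = rng.permutation(25)
            baselines.append(float((A * B[np.ix_(p, p)]).sum()))
        assert res.objective >= np.median(baselines)

    def test_empty_network_yields_empty_result(self):
        res = align(nx.Graph(), nx.complete_graph(3), seed=0)
        assert res.correspondence == {} and res.objective == 0.0


class TestStageSpecificSubnetworks:
    def test_identical_networks_give_empty_outputs(self):
        g = graph([("m1", "g1"), ("g1", "g2")], kinds={"m1": "mirna"})
        res = align(g, g, anchor_labels=True, seed=0)
        sa, sb = stage_specific_subnetworks(g, g, res)
        assert sa.number_of_edges() == 0 and sb.number_of_edges() == 0

    def test_extra_mirna_edge_appears_in_specific_output(self):
        a = graph([("m1", "g1"), ("g1", "g2")], kinds={"m1": "mirna"})
        b = a.copy()
        b.add_node("m2", kind="mirna")
        b.add_edge("m2", "g2", kind="mirna_assoc")
        res = align(a, b, anchor_labels=True, seed=0)
        sa, sb = stage_specific_subnetworks(a, b, res)
        assert sa.number_of_edges() == 0
        assert {frozenset(e) for e in sb.edges()} == {frozenset(("m2", "g2"))}

    def test_no_shared_edge_ever_reported(self):
        a = graph([("m1", "g1"), ("g1", "g2"), ("g2", "g3")], kinds={"m1": "mirna"})
        b = graph([("m1", "g1"), ("g1", "g2"), ("g3", "g4")], kinds={"m1": "mirna"})
        res = align(a, b, anchor_labels=True, seed=0)
        sa, sb = stage_specific_subnetworks(a, b, res)
        shared = set(map(frozenset, a.edges())) & set(map(frozenset, b.edges()))
        assert all(frozenset(e) not in shared for e in sa.edges())
        assert all(frozenset(e) not in shared for e in sb.edges())

    def test_components_without_mirna_dropped(self):
        a = graph([("g1", "g2"), ("m1", "g3")], kinds={"m1": "mirna"})
        b = graph([], nodes=["g1", "g2", "g3", "m1"], kinds={"m1": "mirna"})
        res = align(a, b, anchor_labels=True, seed=0)
        sa, _ = stage_specific_subnetworks(a, b, res)
        assert set(sa.edges()) == {("m1", "g3")}


def test_metrics_table_reference_similarity_na_for_reference():
    nets = {
        "I": graph([("a", "b"), ("b", "c")]),
        "II": graph([("a", "b"), ("c", "d")]),
    }
    table = metrics_table(nets, reference="I")
    assert np.isnan(table.loc["I", "edge_similarity"])
    assert table.loc["II", "edge_similarity"] == pytest.approx(1 / 3)
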