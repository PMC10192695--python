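"""Graph metrics against brute-force oracles and closed forms."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ictalnet.netmetrics import (clustering_coefficient, global_efficiency,
                                 group_summary, mean_shortest_path,
                                 metrics_report, symmetrize, synchronizability)
from ictalnet.stenet import BrainNetwork


def as_net(g):
    return BrainNetwork(graph=nx.DiGraph(g), threshold=0.0,
                        channel_names=list(g.nodes))


# --- independent oracles -----------------------------------------------------

def floyd_warshall_paths(g):
    """All-pairs shortest hops by dynamic programming."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist


def oracle_mean_path(g):
    d = floyd_warshall_paths(g)
    off = d[~np.eye(len(d), dtype=bool)]
    finite = off[np.isfinite(off)]
    return finite.mean() if len(finite) else float("nan")


def oracle_efficiency(g):
    d = floyd_warshall_paths(g)
    off = d[~np.eye(len(d), dtype=bool)]
    inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    return inv.mean()


def oracle_clustering(g):
    vals = []
    for u in g.nodes:
        nbrs = list(g.neighbors(u))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2)
                     if g.has_edge(a, b))
        vals.append(closed / (k * (k - 1) / 2))
    return float(np.mean(vals))


def oracle_eigenratio(g):
    lap = nx.laplacian_matrix(g).toarray().astype(float)
    eig = np.sort(np.linalg.eigvalsh(lap))
    if eig[-1] <= 1e-12 or eig[1] <= 1e-9:
        return 0.0
    return eig[1] / eig[-1]


# --- closed-form cases -------------------------------------------------------

class TestClosedForms:
    def test_path_graph_p3(self):
        net = as_net(nx.path_graph(3))
        val, unreach = mean_shortest_path(net)
        assert val == pytest.approx(4 / 3)
        assert unreach == 0.0

    def test_complete_graph_path_is_one(self):
        assert mean_shortest_path(as_net(nx.complete_graph(5)))[0] == 1.0

    def test_triangle_clustering(self):
        assert clustering_coefficient(as_net(nx.complete_graph(3))) == 1.0

    def test_star_clustering_zero(self):
        assert clustering_coefficient(as_net(nx.star_graph(3))) == 0.0

    def test_complete_graph_efficiency(self):
        assert global_efficiency(as_net(nx.complete_graph(6))) == 1.0

    def test_empty_graph_efficiency(self):
        g = nx.empty_graph(5)
        assert global_efficiency(as_net(g)) == 0.0

    def test_p3_efficiency(self):
        assert global_efficiency(as_net(nx.path_graph(3))) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_eigenratio_one(self, n):
        val, disc = synchronizability(as_net(nx.complete_graph(n)))
        assert val == pytest.approx(1.0)
        assert not disc

    def test_cycle_c4_eigenratio(self):
        # Laplacian eigenvalues of C4: 0, 2, 2, 4
        val, _ = synchronizability(as_net(nx.cycle_graph(4)))
        assert val == pytest.approx(0.5)

    def test_disconnected_graph_flagged(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        val, disc = synchronizability(as_net(g))
        assert val == 0.0 and disc

    def test_no_edges_mean_path_undefined(self):
        val, unreach = mean_shortest_path(as_net(nx.empty_graph(4)))
        assert np.isnan(val) and unreach == 1.0


# --- oracle sweeps -----------------------------------------------------------

def connected_atlas_graphs(max_n=6):
    """Every connected graph on <= max_n nodes, up to isomorphism."""
    from networkx.generators.atlas import graph_atlas_g
    return [g for g in graph_atlas_g()
            if 2 <= g.number_of_nodes() <= max_n and nx.is_connected(g)]


class TestOracleEquivalence:
    def test_all_connected_graphs_up_to_six_nodes(self):
        graphs = connected_atlas_graphs(6)
        assert len(graphs) > 100  # sanity: the sweep is not trivial
        for g in graphs:
            net = as_net(g)
            assert mean_shortest_path(net)[0] == pytest.approx(oracle_mean_path(g))
            assert global_efficiency(net) == pytest.approx(oracle_efficiency(g))
            if g.number_of_nodes() >= 3:
                assert clustering_coefficient(net) == pytest.approx(oracle_clustering(g))
            assert synchronizability(net)[0] == pytest.approx(oracle_eigenratio(g))

    def test_random_graphs_up_to_eight_nodes(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.2, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            net = as_net(g)
            mp, _ = mean_shortest_path(net)
            want = oracle_mean_path(g)
            if np.isnan(want):
                assert np.isnan(mp)
            else:
                assert mp == pytest.approx(want)
            assert global_efficiency(net) == pytest.approx(oracle_efficiency(g))
            assert clustering_coefficient(net) == pytest.approx(oracle_clustering(g))
            assert synchronizability(net)[0] == pytest.approx(oracle_eigenratio(g))


# --- directed handling and summaries ----------------------------------------

class TestSymmetrization:
    def test_max_of_directed_weights(self):
        dg = nx.DiGraph()
        dg.add_edge("a", "b", weight=0.1)
        dg.add_edge("b", "a", weight=0.3)
        g = symmetrize(BrainNetwork(graph=dg, threshold=0.0,
                                    channel_names=["a", "b"]))
        assert g["a"]["b"]["weight"] == 0.3

    def test_weighted_path_uses_inverse_weight(self):
        dg = nx.DiGraph()
        dg.add_edge("a", "b", weight=0.5)
        dg.add_edge("b", "c", weight=0.5)
        dg.add_edge("a", "c", weight=0.2)
        net = BrainNetwork(graph=dg, threshold=0.0, channel_names=list("abc"))
        val, _ = mean_shortest_path(net, mode="weighted")
        # distances: a-b 2, b-c 2, a-c min(5, 4) = 4 -> mean 8/3
        assert val == pytest.approx(8 / 3)


class TestGroupSummary:
    def _report(self, x):
        g = nx.complete_graph(4)
        r = metrics_report(as_net(g), label=x)
        return r

    def test_identical_groups_zero_difference(self):
        rep = {"ictal": [self._report("ictal")] * 3,
               "interictal": [self._report("interictal")] * 3}
        s = group_summary(rep)
        assert all(v == pytest.approx(0.0) for v in s["mean_difference"].values())

    def test_single_report_rejected(self):
        rep = {"ictal": [self._report("ictal")],
               "interictal": [self._report("interictal")] * 2}
        with pytest.raises(ValueError):
            group_summary(rep)

    def test_report_fields(self, ictal_segment):
        from ictalnet.stenet import ste_matrix, threshold_network
        seg, _ = ictal_segment
        net = threshold_network(ste_matrix(seg), 0.02)
        r = metrics_report(net, label="ictal")
        assert r.n_nodes == 23
        assert 0 <= r.clustering_coefficient <= 1
        assert 0 <= r.global_efficiency <= 1
        assert 0 <= r.synchronizability <= 1
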