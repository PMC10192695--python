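"""Graph-theoretic properties of thresholded brain networks.

Four properties distinguish the seizure and between-seizure regimes at the
network level: mean shortest path, clustering coefficient, global
efficiency, and synchronizability (the Laplacian eigenratio lambda_2 /
lambda_max).  All are computed on the symmetrized graph — each undirected
edge takes the larger of the two directed weights, preserving any detected
link — with binary and (where meaningful) weighted variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .stenet import BrainNetwork


@dataclass
class MetricsReport:
    """Per-network summary of the four properties.

    ``unreachable_fraction`` is the share of node pairs with no connecting
    path (those pairs are excluded from the mean shortest path and
    contribute zero to efficiency); ``disconnected`` flags a graph whose
    symmetrized form is not connected, for which the eigenratio is 0.
    """

    mean_shortest_path: float
    clustering_coefficient: float
    global_efficiency: float
    synchronizability: float
    n_nodes: int
    n_edges: int
    density: float
    unreachable_fraction: float = 0.0
    disconnected: bool = False
    label: str = "unknown"


def _as_network(net) -> BrainNetwork:
    if isinstance(net, BrainNetwork):
        return net
    if isinstance(net, nx.Graph):
        return BrainNetwork(graph=nx.DiGraph(net), threshold=0.0,
                            channel_names=list(net.nodes))
    raise TypeError("expected BrainNetwork or networkx graph")


def symmetrize(net) -> nx.Graph:
    """Undirected view: weight of {i, j} is max of the two directed weights."""
    net = _as_network(net)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        w = d.get("weight", 1.0)
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    return g


def _with_distance(g: nx.Graph) -> nx.Graph:
    for _u, _v, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    return g


def mean_shortest_path(net, mode: str = "binary") -> tuple:
    """Average shortest-path length over reachable unordered pairs.

    Binary mode counts hops; weighted mode uses distance = 1/weight.
    Returns ``(value, unreachable_fraction)``; a graph with no edges has no
    defined path length and returns ``(nan, 1.0)``.
    """
    g = symmetrize(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if mode == "binary":
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    elif mode == "weighted":
        lengths = dict(nx.all_pairs_dijkstra_path_length(_with_distance(g),
                                                         weight="distance"))
    else:
        raise ValueError("mode must be binary|weighted")
    vals = [d for u, du in lengths.items() for v, d in du.items() if u != v]
    n_pairs = n * (n - 1)
    unreachable = 1.0 - len(vals) / n_pairs
    if not vals:
        return float("nan"), 1.0
    return float(np.mean(vals)), unreachable


def clustering_coefficient(net, mode: str = "binary") -> float:
    """Mean local clustering on the symmetrized graph.

    Fraction of closed triplets around each node, averaged over all nodes;
    nodes with degree below 2 contribute 0.  Weighted mode uses the
    geometric-mean generalization.
    """
    g = symmetrize(net)
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    weight = None if mode == "binary" else "weight"
    return float(nx.average_clustering(g, weight=weight))


def global_efficiency(net, mode: str = "binary") -> float:
    """Mean inverse shortest-path length over ordered pairs.

    Unreachable pairs contribute 0; a complete binary graph scores 1.
    """
    g = symmetrize(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if mode == "binary":
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    elif mode == "weighted":
        lengths = dict(nx.all_pairs_dijkstra_path_length(_with_distance(g),
                                                         weight="distance"))
    else:
        raise ValueError("mode must be binary|weighted")
    acc = sum(1.0 / d for u, du in lengths.items() for v, d in du.items()
              if u != v and d > 0)
    return acc / (n * (n - 1))


def synchronizability(net) -> tuple:
    """Laplacian eigenratio lambda_2 / lambda_max of the symmetrized binary graph.

    Larger ratios mark networks that synchronize over a wider coupling
    range; a complete graph scores 1.  Disconnected graphs have
    lambda_2 = 0 and return ``(0.0, True)``.
    """
    g = symmetrize(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    a = nx.to_numpy_array(g, weight=None)
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.linalg.eigvalsh(lap)
    lam_max = float(eig[-1])
    lam2 = float(eig[1])
    if lam_max <= 1e-12 or lam2 <= 1e-9 * max(lam_max, 1.0):
        return 0.0, True
    return lam2 / lam_max, False


def metrics_report(net, label: str = "unknown", mode: str = "binary") -> MetricsReport:
    """All four properties of one network in a single report."""
    g = symmetrize(net)
    msp, unreach = mean_shortest_path(net, mode=mode)
    sync, disc = synchronizability(net)
    return MetricsReport(
        mean_shortest_path=msp,
        clustering_coefficient=clustering_coefficient(net, mode="binary"),
        global_efficiency=global_efficiency(net, mode=mode),
        synchronizability=sync,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=(2.0 * g.number_of_edges()
                 / (g.number_of_nodes() * (g.number_of_nodes() - 1))
                 if g.number_of_nodes() > 1 else 0.0),
        unreachable_fraction=unreach,
        disconnected=disc,
        label=label,
    )


_METRIC_FIELDS = ("mean_shortest_path", "clustering_coefficient",
                  "global_efficiency", "synchronizability")


def group_summary(reports_by_label: dict) -> dict:
    """Per-label mean and SD of each metric plus differences of means.

    ``reports_by_label`` maps a label to a list of :class:`MetricsReport`
    (at least two per label).  No hypothesis test is computed — only
    descriptive contrasts.
    """
    for lab, reports in reports_by_label.items():
        if len(reports) < 2:
            raise ValueError(f"need >= 2 reports per label, got {len(reports)} for {lab!r}")
    summary = {"per_label": {}, "mean_difference": {}}
    for lab, reports in reports_by_label.items():
        summary["per_label"][lab] = {
            m: {"mean": float(np.nanmean([getattr(r, m) for r in reports])),
                "sd": float(np.nanstd([getattr(r, m) for r in reports]))}
            for m in _METRIC_FIELDS
        }
    labels = sorted(reports_by_label)
    if len(labels) == 2:
        a, b = labels  # alphabetical: ictal, interictal
        for m in _METRIC_FIELDS:
            summary["mean_difference"][m] = (
                summary["per_label"][a][m]["mean"]
                - summary["per_label"][b][m]["mean"]
            )
    return summary
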