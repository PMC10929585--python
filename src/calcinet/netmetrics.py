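"""Signed weighted graphs from the coupling matrix and robustness metrics.

Positive off-diagonal couplings form the functional-excitatory graph and
negative ones (by absolute value) the functional-inhibitory graph.  Edge
weights are used directly as additive shortest-path lengths, following the
stated library convention: the graph diameter is the maximum weighted
eccentricity over node pairs, and betweenness centrality is the fraction
of all-pairs weighted shortest paths passing through a node.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import FunctionalConnectivity

__all__ = [
    "SignedGraphPair",
    "NetworkSummary",
    "split_signed_graph",
    "graph_diameter",
    "betweenness",
    "betweenness_change_table",
    "detect_communities",
    "summarize_network",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SignedGraphPair:
    """Functional-excitatory and functional-inhibitory weighted graphs.

    Both graphs share the node set; edge sets are disjoint as
    (source, target) pairs, weights strictly positive, no self-loops.
    """

    excitatory: nx.DiGraph | nx.Graph
    inhibitory: nx.DiGraph | nx.Graph
    directed: bool = True

    @property
    def nodes(self) -> list:
        return list(self.excitatory.nodes)


@dataclasses.dataclass
class NetworkSummary:
    diameter_exc: float
    diameter_inh: float
    coverage_exc: float
    coverage_inh: float
    betweenness_exc: dict
    betweenness_inh: dict
    communities_exc: list[set]
    communities_inh: list[set]
    modularity_exc: float
    modularity_inh: float

    def to_dict(self) -> dict:
        return {
            "diameter": {"excitatory": self.diameter_exc, "inhibitory": self.diameter_inh},
            "component_coverage": {"excitatory": self.coverage_exc, "inhibitory": self.coverage_inh},
            "betweenness": {
                "excitatory": {str(k): v for k, v in self.betweenness_exc.items()},
                "inhibitory": {str(k): v for k, v in self.betweenness_inh.items()},
            },
            "communities": {
                "excitatory": [sorted(map(str, c)) for c in self.communities_exc],
                "inhibitory": [sorted(map(str, c)) for c in self.communities_inh],
            },
            "modularity": {"excitatory": self.modularity_exc, "inhibitory": self.modularity_inh},
        }


def split_signed_graph(
    fc: FunctionalConnectivity | np.ndarray,
    directed: bool = True,
    weight_floor: float = 0.0,
) -> SignedGraphPair:
    """Split T into excitatory (T_ij > 0) and inhibitory (|T_ij|, T_ij < 0).

    Edge direction is j -> i for entry T[i, j] (signal sent from j to i);
    the diagonal is ignored.  ``weight_floor`` optionally drops edges with
    |T_ij| below it (visualization parity; default keeps all).
    """
    if isinstance(fc, FunctionalConnectivity):
        T = fc.T
        nodes = list(fc.neuron_ids)
    else:
        T = np.asarray(fc, dtype=float)
        nodes = list(range(T.shape[0]))
    n = T.shape[0]
    gcls = nx.DiGraph if directed else nx.Graph
    exc, inh = gcls(), gcls()
    exc.add_nodes_from(nodes)
    inh.add_nodes_from(nodes)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = T[i, j]
            if abs(w) <= weight_floor or w == 0.0:
                continue
            if w > 0:
                exc.add_edge(nodes[j], nodes[i], weight=float(w))
            else:
                inh.add_edge(nodes[j], nodes[i], weight=float(-w))
    return SignedGraphPair(excitatory=exc, inhibitory=inh, directed=directed)


def graph_diameter(g: nx.Graph | nx.DiGraph) -> tuple[float, float]:
    """Weighted diameter on the largest (strongly) connected component.

    Distances are sums of edge weights along shortest paths; the returned
    coverage is the fraction of nodes inside the component used.  An
    edgeless graph yields (0, 1/N) with a warning.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("graph has no nodes")
    if g.number_of_edges() == 0:
        if n > 1:
            logger.warning("edgeless graph: diameter reported as 0 on a single node")
        return 0.0, 1.0 / n
    comps = (
        nx.strongly_connected_components(g) if g.is_directed() else nx.connected_components(g)
    )
    comp = max(comps, key=len)
    sub = g.subgraph(comp)
    if sub.number_of_nodes() == 1:
        logger.warning("largest component is a single node; diameter 0")
        return 0.0, 1.0 / n
    diam = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(sub, weight="weight"):
        ecc = max(dists.values())
        diam = max(diam, ecc)
    return float(diam), len(comp) / n


def betweenness(g: nx.Graph | nx.DiGraph) -> dict:
    """Normalized weighted-shortest-path betweenness (endpoints excluded)."""
    return nx.betweenness_centrality(g, weight="weight", normalized=True)


def betweenness_change_table(
    before: Mapping | NetworkSummary,
    after: Mapping | NetworkSummary,
    top_k: int = 5,
    graph: str = "excitatory",
) -> pd.DataFrame:
    """Top-k nodes by absolute betweenness change between conditions.

    ``before``/``after`` may be NetworkSummary objects or plain
    node -> score mappings.  Ties in |change| break by ascending node id.
    """
    if isinstance(before, NetworkSummary):
        before = before.betweenness_exc if graph == "excitatory" else before.betweenness_inh
    if isinstance(after, NetworkSummary):
        after = after.betweenness_exc if graph == "excitatory" else after.betweenness_inh
    if set(before) != set(after):
        raise ValueError("node sets must match")
    rows = [
        {
            "neuron": node,
            "score_before": before[node],
            "score_after": after[node],
            "abs_change": abs(after[node] - before[node]),
        }
        for node in before
    ]
    df = pd.DataFrame(rows).sort_values(
        ["abs_change", "neuron"], ascending=[False, True], kind="mergesort"
    )
    return df.head(top_k).reset_index(drop=True)


def _undirected_projection(g: nx.Graph | nx.DiGraph) -> nx.Graph:
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    return und


def detect_communities(g: nx.Graph | nx.DiGraph, seed: int = 0) -> tuple[list[set], float]:
    """Louvain modularity communities on the undirected weighted projection.

    Edgeless graphs return singleton communities with modularity 0.
    """
    und = _undirected_projection(g)
    if und.number_of_edges() == 0:
        return [{node} for node in und.nodes], 0.0
    parts = nx.algorithms.community.louvain_communities(und, weight="weight", seed=seed)
    q = nx.algorithms.community.modularity(und, parts, weight="weight")
    return [set(p) for p in parts], float(q)


def summarize_network(pair: SignedGraphPair, seed: int = 0) -> NetworkSummary:
    """Diameter, betweenness, and communities for both signed graphs."""
    d_exc, cov_exc = graph_diameter(pair.excitatory)
    d_inh, cov_inh = graph_diameter(pair.inhibitory)
    comm_exc, q_exc = detect_communities(pair.excitatory, seed=seed)
    comm_inh, q_inh = detect_communities(pair.inhibitory, seed=seed)
    return NetworkSummary(
        diameter_exc=d_exc,
        diameter_inh=d_inh,
        coverage_exc=cov_exc,
        coverage_inh=cov_inh,
        betweenness_exc=betweenness(pair.excitatory),
        betweenness_inh=betweenness(pair.inhibitory),
        communities_exc=comm_exc,
        communities_inh=comm_inh,
        modularity_exc=q_exc,
        modularity_inh=q_inh,
    )
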