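import numpy as np
import pytest

from calcinet import (
    fit_connectivity,
    make_ground_truth_network,
    simulate_sessions,
)


@pytest.fixture(scope="session")
def small_net():
    """A stable 5-neuron full-rank ground-truth network."""
    return make_ground_truth_network(5, 5, seed=11)


@pytest.fixture(scope="session")
def medium_net():
    """A stable 20-neuron full-rank ground-truth network."""
    return make_ground_truth_network(20, 20, seed=7)


@pytest.fixture(scope="session")
def recovered_small(small_net):
    """Noise-free fit of the small network from restarted sessions."""
    sessions = simulate_sessions(small_net, n_sessions=8, frames_per_session=50, seed=3, clip=False)
    return fit_connectivity(sessions)


def random_weighted_digraph(n, p, rng):
    """Random directed graph with uniform weights; independent of the package."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
    return g


def floyd_warshall_distances(g):
    """All-pairs shortest path lengths by the classic cubic recurrence."""
    nodes = list(g.nodes)
    idx = {u: k for k, u in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in g.edges(data=True):
        d[idx[u], idx[v]] = min(d[idx[u], idx[v]], data["weight"])
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return nodes, d


def brute_force_betweenness(g, tol=1e-9):
    """Betweenness by exhaustive simple-path enumeration (graphs <= 8 nodes).

    For each ordered pair (s, t), enumerates every simple path, finds the
    minimum total weight, and counts how many minimum-weight paths pass
    through each intermediate node.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    scores = {v: 0.0 for v in nodes}
    adj = {u: [(v, g[u][v]["weight"]) for v in g.successors(u)] for u in nodes} if g.is_directed() else {
        u: [(v, g[u][v]["weight"]) for v in g.neighbors(u)] for u in nodes
    }

    def all_paths(s, t):
        paths = []

        def extend(path, cost, seen):
            u = path[-1]
            if u == t:
                paths.append((cost, tuple(path)))
                return
            for v, w in adj[u]:
                if v not in seen:
                    extend(path + [v], cost + w, seen | {v})

        extend([s], 0.0, {s})
        return paths

    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(c for c, _ in paths)
            shortest = [p for c, p in paths if c <= best + tol]
            sigma = len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    scores[v] += 1.0 / sigma
    if g.is_directed():
        norm = (n - 1) * (n - 2)
    else:
        norm = (n - 1) * (n - 2) / 2
    if norm > 0:
        scores = {v: s / norm for v, s in scores.items()}
    return scores
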