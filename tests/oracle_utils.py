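"""Independent reference implementations used to check the package.

Everything here is deliberately naive — plain dict/set enumeration and
dense linear algebra — and shares no code path with the package's
sparse/vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from netprio.network_io import GeneNetwork


def edge_map(network: GeneNetwork) -> dict[str, dict[str, float]]:
    """Neighbor map rebuilt from the edge iterator only."""
    adj: dict[str, dict[str, float]] = {g: {} for g in network.nodes}
    for a, b, w in network.edges():
        adj[a][b] = w
        adj[b][a] = w
    return adj


def naive_icn(adj: dict[str, dict[str, float]], i: str, j: str, formula: str = "product") -> float:
    """Term-by-term ICN from a neighbor map: direct weight + normalized connector sum."""
    w_ij = adj[i].get(j, 0.0)
    connectors = set(adj[i]) & set(adj[j])
    if formula == "product":
        conn = sum(adj[i][u] * adj[u][j] for u in connectors)
    elif formula == "average":
        conn = sum((adj[i][u] + adj[u][j]) / 2.0 for u in connectors)
    else:
        raise ValueError(formula)
    if conn == 0.0:
        return w_ij
    k_i = sum(adj[i].values())
    k_j = sum(adj[j].values())
    total = sum(sum(nbrs.values()) for nbrs in adj.values())
    expected = k_i * k_j / total
    return w_ij + conn / expected


def naive_candidate_scores(
    adj: dict[str, dict[str, float]], seeds, candidates, formula: str = "product"
) -> dict[str, float]:
    return {
        c: sum(naive_icn(adj, c, s, formula) for s in seeds if s != c) for c in candidates
    }


def dense_rw_solve(network: GeneNetwork, seeds, restart: float) -> np.ndarray:
    """Stationary RW scores by solving (I - (1-r) W) p = r p0 densely."""
    nodes = network.nodes
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((n, n))
    strengths = {g: sum(network.neighbors(g).values()) for g in nodes}
    for a, b, w in network.edges():
        W[idx[b], idx[a]] = w / strengths[a]  # column a distributes to neighbor b
        W[idx[a], idx[b]] = w / strengths[b]
    for g in nodes:
        if strengths[g] == 0:
            W[idx[g], idx[g]] = 1.0
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(set(seeds))
    return np.linalg.solve(np.eye(n) - (1.0 - restart) * W, restart * p0)


def dense_prince_solve(network: GeneNetwork, seeds, alpha: float) -> np.ndarray:
    """PR limit (1 - alpha)(I - alpha W')^-1 Y by dense solve."""
    nodes = network.nodes
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    Wn = np.zeros((n, n))
    strengths = {g: sum(network.neighbors(g).values()) for g in nodes}
    for a, b, w in network.edges():
        v = w / np.sqrt(strengths[a] * strengths[b])
        Wn[idx[a], idx[b]] = v
        Wn[idx[b], idx[a]] = v
    y = np.zeros(n)
    for s in set(seeds):
        y[idx[s]] = 1.0
    return np.linalg.solve(np.eye(n) - alpha * Wn, (1.0 - alpha) * y)


def random_network(rng: np.random.Generator, max_nodes: int, weighted: bool) -> GeneNetwork:
    """Small Erdos-Renyi-style network with at least one edge."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.6))
        edges = []
        names = [f"g{i:02d}" for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w = float(rng.uniform(0.05, 1.0)) if weighted else 1.0
                    edges.append((names[i], names[j], w))
        if edges:
            return GeneNetwork.from_edges(edges, weighted=weighted, extra_nodes=names)
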