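"""Shared fixtures and brute-force oracles.

The oracles are deliberately naive (exhaustive enumeration) and independent
of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def worked_example() -> tuple[nx.Graph, list[str]]:
    """Five-node example: two candidate nodes N1/N2 and three seeds G1-G3.

    N1 touches all three seeds (0.850, 0.900, 0.950); N2 touches only G1
    (0.950) and G2 (0.900).
    """
    g = nx.Graph()
    g.add_edge("N1", "G1", weight=0.850)
    g.add_edge("N1", "G2", weight=0.900)
    g.add_edge("N1", "G3", weight=0.950)
    g.add_edge("N2", "G1", weight=0.950)
    g.add_edge("N2", "G2", weight=0.900)
    return g, ["G1", "G2", "G3"]


@pytest.fixture
def planted_clique() -> tuple[nx.Graph, list[str], set[str]]:
    """8-node clique (uniform weight 0.95) + 8 weaker background nodes.

    Background edges stay at or below 0.82 and attach the background chain to
    the clique so the whole graph is connected.
    """
    g = nx.Graph()
    clique = [f"C{i}" for i in range(8)]
    for a, b in itertools.combinations(clique, 2):
        g.add_edge(a, b, weight=0.95)
    bg = [f"B{i}" for i in range(8)]
    rng = np.random.default_rng(42)
    for i, node in enumerate(bg):
        anchor = clique[i % 8] if i < 3 else bg[i - 3]
        g.add_edge(node, anchor, weight=float(rng.uniform(0.70, 0.82)))
    for a, b in [("B0", "B4"), ("B1", "B6"), ("B2", "B7")]:
        g.add_edge(a, b, weight=float(rng.uniform(0.70, 0.82)))
    return g, ["C0", "C3", "C5"], set(clique)


def random_weighted_graph(
    seed: int,
    n_max: int = 8,
    p: float = 0.45,
    connected: bool = True,
    max_edges: int | None = None,
) -> nx.Graph:
    """Small random weighted graph for oracle comparisons (weights in (0.5, 0.999]).

    ``max_edges`` keeps 2^E subgraph enumerations tractable.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    while True:
        g = nx.Graph()
        g.add_nodes_from(f"v{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(f"v{i}", f"v{j}", weight=float(rng.uniform(0.5, 0.999)))
        if max_edges is not None and g.number_of_edges() > max_edges:
            continue
        if not connected or (g.number_of_nodes() and nx.is_connected(g)):
            return g


def brute_force_shortest_distance(g: nx.Graph, source: str, target: str) -> float:
    """Minimum 1-w path distance over ALL simple paths (exhaustive)."""
    if source == target:
        return 0.0
    best = math.inf
    for path in nx.all_simple_paths(g, source, target):
        d = sum(1.0 - g[a][b]["weight"] for a, b in zip(path, path[1:]))
        best = min(best, d)
    return best


def brute_force_reachable(g: nx.Graph, source: str, max_len: int) -> set[str]:
    """Nodes reachable by some simple path of <= max_len edges (exhaustive DFS)."""
    found = {source}

    def walk(node: str, used: set[str], depth: int) -> None:
        if depth == max_len:
            return
        for nbr in g[node]:
            if nbr not in used:
                found.add(nbr)
                walk(nbr, used | {nbr}, depth + 1)

    walk(source, {source}, 0)
    return found


def brute_force_max_avg_weight(g: nx.Graph) -> float:
    """Maximum mean edge weight over all connected spanning subgraphs (2^E scan)."""
    idx = {node: i for i, node in enumerate(g.nodes)}
    edges = [(idx[a], idx[b], w) for a, b, w in g.edges(data="weight")]
    n, m = len(idx), len(edges)
    best = -math.inf
    for mask in range(1, 1 << m):
        chosen = [edges[i] for i in range(m) if mask >> i & 1]
        if len(chosen) < n - 1:
            continue
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        comps = n
        for a, b, _ in chosen:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                comps -= 1
        if comps == 1:
            best = max(best, sum(w for _, _, w in chosen) / len(chosen))
    return best
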