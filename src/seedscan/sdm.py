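"""Customized steepest-descent extraction of a dense seed-containing subnetwork.

The search iteratively deletes the node that is *least relevant* to the seed
proteins, under a connectivity guard that never lets the seeds fall into
different components:

* **distance phase** — while some nodes lack a direct seed edge, the node
  whose shortest-path distance to the nearest seed (edge distance = 1 - w,
  Dijkstra) is largest is removed;
* **aggregate phase** — once every remaining node touches a seed directly,
  the node whose summed direct-edge weight to the seeds is smallest is
  removed instead, since distances no longer discriminate.

Once the shrinking network is at or below a size threshold, each snapshot's
weighted density

    D_n = sum(w_ij * e_ij) / (n * (n - 1) / 2)

is recorded.  The densest few snapshots are kept as candidates; the largest
of them is the default final network.  Each candidate is then pruned: the
least-weighted non-bridge edge is removed while doing so raises the average
edge weight

    W_n = sum(w_ij * e_ij) / sum(e_ij)

and the pruned candidates are ranked by total retained weight

    S_n = sum(w_ij * e_ij).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .preprocess import SeedSet
from .scoring import INFINITE_DISTANCE

__all__ = [
    "CandidateNetwork",
    "DescentStep",
    "DescentTrace",
    "dijkstra_distances",
    "seed_distances",
    "seed_distance",
    "aggregate_score",
    "ranked_candidates",
    "select_candidate_node",
    "remove_with_guard",
    "density",
    "average_weight",
    "network_score",
    "descend",
    "select_final",
    "prune_edges",
    "rank_networks",
    "DEFAULT_SIZE_THRESHOLD",
    "DEFAULT_KEEP",
    "DEFAULT_TOP_N",
]

DEFAULT_SIZE_THRESHOLD = 50
DEFAULT_KEEP = 5
DEFAULT_TOP_N = 5

PHASE_DISTANCE = "distance"
PHASE_AGGREGATE = "aggregate"


# ---------------------------------------------------------------------------
# candidate networks


@dataclass(frozen=True)
class CandidateNetwork:
    """A connected node subset with its induced weighted edges and statistics."""

    graph: nx.Graph
    density: float
    avg_weight: float
    score: float

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "CandidateNetwork":
        return cls(
            graph=graph,
            density=density(graph) if graph.number_of_nodes() >= 2 else 0.0,
            avg_weight=average_weight(graph) if graph.number_of_edges() else 0.0,
            score=network_score(graph),
        )

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    def recompute(self) -> tuple[float, float, float]:
        """Recompute (density, avg_weight, score) from the raw edges."""
        return (
            density(self.graph),
            average_weight(self.graph) if self.graph.number_of_edges() else 0.0,
            network_score(self.graph),
        )

    def _sort_key(self) -> tuple:
        return (self.size, self.density, tuple(sorted(self.nodes)))


@dataclass(frozen=True)
class DescentStep:
    removed: str
    phase: str
    criterion: float
    size_after: float
    density_after: float


@dataclass
class DescentTrace:
    """Ordered record of the descent plus the densest recorded snapshots."""

    steps: list[DescentStep] = field(default_factory=list)
    recorded_candidates: list[CandidateNetwork] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "removed": s.removed,
                    "phase": s.phase,
                    "criterion": None if math.isinf(s.criterion) else s.criterion,
                    "size_after": s.size_after,
                    "density_after": s.density_after,
                }
                for s in self.steps
            ],
            "recorded_candidates": [
                {
                    "size": c.size,
                    "density": c.density,
                    "nodes": sorted(c.nodes),
                }
                for c in self.recorded_candidates
            ],
        }


# ---------------------------------------------------------------------------
# distances and scores


def dijkstra_distances(network: nx.Graph, source: str) -> dict[str, float]:
    """Single-source shortest-path distances under the 1 - w edge distance.

    Unreachable nodes map to the infinite-distance sentinel.
    """
    if source not in network:
        raise KeyError(f"source {source!r} not in network")
    reached = nx.single_source_dijkstra_path_length(
        network, source, weight=lambda u, v, d: 1.0 - d["weight"]
    )
    return {n: reached.get(n, INFINITE_DISTANCE) for n in network.nodes}


def seed_distances(network: nx.Graph, seeds: SeedSet | Iterable[str]) -> dict[str, float]:
    """Distance of every node to its *nearest* seed (multi-source Dijkstra)."""
    seed_nodes = [s for s in _seed_iter(seeds) if s in network]
    if not seed_nodes:
        raise ValueError("no seed protein present in the network")
    reached = nx.multi_source_dijkstra_path_length(
        network, seed_nodes, weight=lambda u, v, d: 1.0 - d["weight"]
    )
    return {n: reached.get(n, INFINITE_DISTANCE) for n in network.nodes}


def seed_distance(node: str, seeds: SeedSet | Iterable[str], network: nx.Graph) -> float:
    """Shortest-path distance from ``node`` to the nearest seed protein.

    The seed set stands in for the unknown target network, and a node's
    relevance is its distance to the closest member; a node unreachable from
    every seed gets the infinite sentinel (making it the immediate removal
    candidate).
    """
    seed_nodes = set(_seed_iter(seeds))
    if node in seed_nodes:
        raise ValueError(f"{node!r} is itself a seed")
    return seed_distances(network, seed_nodes)[node]


def aggregate_score(node: str, seeds: SeedSet | Iterable[str], network: nx.Graph) -> float:
    """Summed weight of direct edges between ``node`` and the seed proteins."""
    seed_nodes = set(_seed_iter(seeds))
    if node in seed_nodes:
        raise ValueError(f"{node!r} is itself a seed")
    total = 0.0
    for nbr in network[node]:
        if nbr in seed_nodes:
            total += network[node][nbr]["weight"]
    return total


def _seed_iter(seeds: SeedSet | Iterable[str]) -> Iterable[str]:
    if isinstance(seeds, SeedSet):
        return seeds.all
    return seeds


# ---------------------------------------------------------------------------
# candidate selection and guarded removal


def ranked_candidates(
    network: nx.Graph, seeds: SeedSet | Iterable[str]
) -> list[tuple[str, str, float]]:
    """Non-seed nodes ranked best-removal-first as (node, phase, criterion).

    Distance phase while any non-seed node lacks a direct seed edge: rank by
    nearest-seed distance descending.  Aggregate phase once every non-seed
    node touches a seed: rank by summed direct seed-edge weight ascending.
    Ties break lexicographically by identifier.
    """
    seed_nodes = set(_seed_iter(seeds))
    others = sorted(set(network.nodes) - seed_nodes)
    if not others:
        return []

    all_adjacent = all(
        any(nbr in seed_nodes for nbr in network[n]) for n in others
    )
    if all_adjacent:
        scored = [(aggregate_score(n, seed_nodes, network), n) for n in others]
        scored.sort(key=lambda t: (t[0], t[1]))
        return [(n, PHASE_AGGREGATE, v) for v, n in scored]

    dist = seed_distances(network, seed_nodes)
    ranked = sorted(((dist[n], n) for n in others), key=lambda t: (-t[0], t[1]))
    return [(n, PHASE_DISTANCE, d) for d, n in ranked]


def select_candidate_node(
    network: nx.Graph, seeds: SeedSet | Iterable[str]
) -> tuple[str, str]:
    """The single best removal candidate and the phase that chose it."""
    ranked = ranked_candidates(network, seeds)
    if not ranked:
        raise StopIteration("only seed proteins remain; descent terminates")
    node, phase, _ = ranked[0]
    return node, phase


def seeds_connected(network: nx.Graph, seeds: SeedSet | Iterable[str]) -> bool:
    """True when every seed lies in one connected component."""
    seed_nodes = [s for s in _seed_iter(seeds) if s in network]
    if not seed_nodes:
        return False
    component = nx.node_connected_component(network, seed_nodes[0])
    return all(s in component for s in seed_nodes[1:])


def remove_with_guard(
    network: nx.Graph, seeds: SeedSet | Iterable[str], candidate: str
) -> nx.Graph | None:
    """Remove ``candidate`` unless doing so disconnects the seed proteins.

    Returns the reduced graph, or ``None`` (rejection) so the caller can try
    the next-ranked candidate.
    """
    seed_nodes = set(_seed_iter(seeds))
    if candidate in seed_nodes:
        raise ValueError(f"cannot remove seed protein {candidate!r}")
    reduced = network.copy()
    reduced.remove_node(candidate)
    if not seeds_connected(reduced, seed_nodes):
        return None
    return reduced


# ---------------------------------------------------------------------------
# network statistics


def density(network: nx.Graph) -> float:
    """Weighted density: total edge weight over the n(n-1)/2 possible edges."""
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError(f"density undefined for n={n} (< 2 nodes)")
    total = network.size(weight="weight")
    return total / (n * (n - 1) / 2.0)


def average_weight(network: nx.Graph) -> float:
    """Mean weight of the edges currently present."""
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("average weight undefined for a network with no edges")
    return network.size(weight="weight") / m


def network_score(network: nx.Graph) -> float:
    """Total retained edge weight (the ranking score of a pruned network)."""
    return float(network.size(weight="weight"))


# ---------------------------------------------------------------------------
# descent


def descend(
    network: nx.Graph,
    seeds: SeedSet | Iterable[str],
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
    keep: int = DEFAULT_KEEP,
) -> tuple[DescentTrace, list[CandidateNetwork]]:
    """Run the guarded steepest descent and return the densest snapshots.

    Nodes are removed one at a time (seeds never) until only seeds remain or
    every remaining candidate is rejected by the connectivity guard.  Every
    connected snapshot of size <= ``size_threshold`` (including the starting
    network if it already qualifies) is recorded with its density; the
    ``keep`` densest are returned, sorted by density descending.
    """
    seed_nodes = frozenset(_seed_iter(seeds))
    missing = sorted(s for s in seed_nodes if s not in network)
    if missing:
        raise ValueError(f"seed proteins not in network: {missing}")
    if not seeds_connected(network, seed_nodes):
        raise ValueError(
            "seed proteins are not mutually connected in the working network; "
            "lower the score threshold or increase the path length"
        )
    if size_threshold < len(seed_nodes):
        raise ValueError("size_threshold smaller than the seed set")
    if keep < 1:
        raise ValueError("keep must be >= 1")

    current = network.copy()
    trace = DescentTrace()
    recorded: list[CandidateNetwork] = []

    def record(g: nx.Graph) -> None:
        if g.number_of_nodes() <= size_threshold and g.number_of_nodes() >= 2:
            if nx.is_connected(g):
                recorded.append(CandidateNetwork.from_graph(g.copy()))

    record(current)

    while True:
        ranked = ranked_candidates(current, seed_nodes)
        accepted = False
        for node, phase, value in ranked:
            reduced = remove_with_guard(current, seed_nodes, node)
            if reduced is None:
                continue
            current = reduced
            assert seeds_connected(current, seed_nodes)
            d_after = density(current) if current.number_of_nodes() >= 2 else 0.0
            trace.steps.append(
                DescentStep(
                    removed=node,
                    phase=phase,
                    criterion=value,
                    size_after=current.number_of_nodes(),
                    density_after=d_after,
                )
            )
            record(current)
            accepted = True
            break
        if not accepted:
            break  # only seeds remain, or every candidate is guarded

    if not recorded:
        # nothing ever fell below the size threshold; keep the terminal state
        recorded.append(CandidateNetwork.from_graph(current.copy()))

    # round away float accumulation noise so genuine density ties break by size
    recorded.sort(key=lambda c: (-round(c.density, 9), -c.size, tuple(sorted(c.nodes))))
    top = recorded[:keep]
    trace.recorded_candidates = top
    return trace, top


def select_final(candidates: Sequence[CandidateNetwork]) -> CandidateNetwork:
    """The largest candidate among the densest few (density balances size).

    Ties on size break toward higher density, then lexicographic node order.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    return max(
        candidates,
        key=lambda c: (c.size, c.density, tuple(sorted(c.nodes, reverse=True))),
    )


# ---------------------------------------------------------------------------
# edge pruning and ranking


def prune_edges(
    candidate: CandidateNetwork,
    rng_seed: int,
    return_trace: bool = False,
) -> CandidateNetwork | tuple[CandidateNetwork, list[float]]:
    """Remove least-weighted edges until the average weight peaks.

    Repeatedly deletes the minimum-weight edge whose removal both keeps the
    network connected and strictly increases W_n; among equal-minimum edges
    one is picked at random (``rng_seed`` drives the draw).  The node set is
    unchanged and the result is connected.  With ``return_trace=True`` the
    sequence of W_n values after each removal is returned as well.
    """
    g = candidate.graph.copy()
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("candidate network must be connected")
    rng = np.random.default_rng(rng_seed)
    w_trace: list[float] = []
    if g.number_of_edges():
        w_trace.append(average_weight(g))

    while g.number_of_edges() > 1:
        w_bar = average_weight(g)
        bridges = set(map(frozenset, nx.bridges(g)))
        removable = [
            (d["weight"], u, v)
            for u, v, d in g.edges(data=True)
            if frozenset((u, v)) not in bridges
        ]
        if not removable:
            break
        removable.sort(key=lambda t: t[0])
        w_min = removable[0][0]
        if w_min >= w_bar:
            break  # removing any edge would not increase the average weight
        ties = [e for e in removable if e[0] == w_min]
        pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        g.remove_edge(pick[1], pick[2])
        w_trace.append(average_weight(g))

    pruned = CandidateNetwork.from_graph(g)
    if return_trace:
        return pruned, w_trace
    return pruned


def rank_networks(
    pruned: Sequence[CandidateNetwork], top_n: int = DEFAULT_TOP_N
) -> list[CandidateNetwork]:
    """Sort pruned candidates by total retained weight S_n, highest first.

    Equal scores order by larger size, then lexicographic node set.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = sorted(
        pruned,
        key=lambda c: (-round(c.score, 9), -c.size, tuple(sorted(c.nodes))),
    )
    return list(ordered[:top_n])
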