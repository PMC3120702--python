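"""Seed-relevant scoping and automatic seed expansion.

Two pre-processing steps reduce the search substrate before the descent:

1. *Common scope* — every node connected to **each** given seed within a
   bounded number of hops is kept (set intersection over seeds), so the
   working graph only contains proteins plausibly between the seeds.
2. *Seed expansion* — a non-seed protein with at least three interactions
   with the given seeds, or at least two highly credible ones (weight at
   or above the credible threshold), is promoted to a seed and becomes part
   of the reported network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

__all__ = [
    "SeedSet",
    "read_seed_list",
    "dfs_scope",
    "common_scope",
    "expand_seeds",
    "DEFAULT_PATH_LENGTH",
    "DEFAULT_CREDIBLE_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_PATH_LENGTH = 10
DEFAULT_CREDIBLE_THRESHOLD = 0.980

#: provenance tags for promoted seeds
PROV_USER = "user"
PROV_THREE_EDGES = "three_edges"
PROV_TWO_CREDIBLE = "two_credible_edges"


@dataclass
class SeedSet:
    """User-supplied seed proteins plus any automatically promoted ones."""

    given: frozenset[str]
    expanded: frozenset[str] = frozenset()
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.given = frozenset(self.given)
        self.expanded = frozenset(self.expanded)
        if self.given & self.expanded:
            raise ValueError("given and expanded seed sets overlap")
        for s in self.given:
            self.provenance.setdefault(s, PROV_USER)

    @property
    def all(self) -> frozenset[str]:
        return self.given | self.expanded

    def __contains__(self, node: str) -> bool:
        return node in self.given or node in self.expanded

    def __iter__(self):
        return iter(sorted(self.all))

    def __len__(self) -> int:
        return len(self.given) + len(self.expanded)


def read_seed_list(stream: IO[str]) -> SeedSet:
    """Read a plain seed list: one identifier per line, ``#`` comments allowed."""
    seeds = []
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if line:
            seeds.append(line)
    if not seeds:
        raise ValueError("seed list is empty")
    return SeedSet(given=frozenset(seeds))


def dfs_scope(network: nx.Graph, source: str, max_path_length: int) -> set[str]:
    """All nodes reachable from ``source`` within ``max_path_length`` hops.

    Hop count ignores edge weights (the bound is over path length, applied
    before any weight-to-distance conversion).  ``source`` itself is included.
    """
    if source not in network:
        raise KeyError(f"seed protein {source!r} is not in the network")
    if max_path_length < 1:
        raise ValueError(f"max_path_length must be >= 1, got {max_path_length}")
    return set(nx.single_source_shortest_path_length(network, source, cutoff=max_path_length))


def common_scope(network: nx.Graph, seeds: SeedSet, max_path_length: int) -> nx.Graph:
    """Induced subgraph on nodes within scope of *every* given seed, plus the seeds.

    The intersection is taken over the user-given seeds only (scoping happens
    before expansion).  Seeds are always retained, even if the intersection is
    otherwise empty (a warning is logged in that case).
    """
    for s in seeds.given:
        if s not in network:
            raise KeyError(f"seed protein {s!r} is not in the network")
    scopes = [dfs_scope(network, s, max_path_length) for s in sorted(seeds.given)]
    common: set[str] = set.intersection(*scopes) if scopes else set()
    if not common - seeds.all:
        logger.warning(
            "common scope at path length %d contains no non-seed protein; "
            "consider increasing the path length", max_path_length,
        )
    keep = common | seeds.all
    return network.subgraph(keep & set(network.nodes)).copy()


def _promotion(
    network: nx.Graph, node: str, seed_nodes: frozenset[str], credible_threshold: float
) -> str | None:
    """Return the promotion rule ``node`` satisfies against ``seed_nodes``, if any."""
    n_edges = 0
    n_credible = 0
    for nbr in network[node]:
        if nbr in seed_nodes:
            n_edges += 1
            if network[node][nbr]["weight"] >= credible_threshold:
                n_credible += 1
    if n_edges >= 3:
        return PROV_THREE_EDGES
    if n_credible >= 2:
        return PROV_TWO_CREDIBLE
    return None


def expand_seeds(
    network: nx.Graph,
    seeds: SeedSet,
    credible_threshold: float = DEFAULT_CREDIBLE_THRESHOLD,
    cascade: bool = False,
) -> SeedSet:
    """Promote strongly seed-connected proteins to seeds.

    A non-seed node is promoted when it has >= 3 edges to the given seeds,
    or >= 2 edges of weight >= ``credible_threshold`` to them.  The default
    is a single pass counting edges to the *user-given* seeds only, which
    makes the operation idempotent.  ``cascade=True`` instead iterates to a
    fixed point counting edges to the growing seed set; on dense networks
    this can promote far beyond the pathway, so it is off by default.
    """
    if not 0.0 < credible_threshold < 1.0:
        raise ValueError(f"credible_threshold {credible_threshold} outside (0, 1)")
    current = frozenset(s for s in seeds.all if s in network)
    base = current if cascade else frozenset(s for s in seeds.given if s in network)
    expanded = dict(seeds.provenance)
    new_expanded = set(seeds.expanded)

    while True:
        promoted_this_pass = []
        for node in sorted(set(network.nodes) - current):
            rule = _promotion(network, node, base, credible_threshold)
            if rule is not None:
                promoted_this_pass.append((node, rule))
        if not promoted_this_pass:
            break
        for node, rule in promoted_this_pass:
            new_expanded.add(node)
            expanded[node] = rule
            logger.info("promoted %s to seed via %s", node, rule)
        current = current | {n for n, _ in promoted_this_pass}
        if not cascade:
            break
        base = current

    return SeedSet(
        given=seeds.given,
        expanded=frozenset(new_expanded - seeds.given),
        provenance=expanded,
    )
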