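"""Synthetic interactomes with a planted high-weight pathway module.

The generator emulates the structural assumptions behind seed-driven
subnetwork extraction: proteins of one signalling pathway interact more
often, and more strongly, with each other than with the rest of the
interactome.  A dense high-weight module (the planted pathway) is embedded
in a sparse lower-weight background; optional decoy modules are as dense as
the pathway but carry only background-strength weights, so recovering a
decoy instead of the pathway indicates a weight-insensitive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .evaluation import ReferencePathway
from .preprocess import SeedSet
from .scoring import MAX_SCORE

__all__ = ["SyntheticSpec", "generate", "pick_seeds"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-pathway generator.

    Weight ranges are closed intervals inside (0, 0.999]; the pathway range
    must sit strictly above the background range (the separation assumption).
    Lower ``pathway_weight_range`` bounds let tests probe the overlap regime
    where that assumption fails.
    """

    pathway_size: int = 15
    background_size: int = 85
    pathway_edge_prob: float = 0.6
    background_edge_prob: float = 0.05
    cross_edge_prob: float = 0.05
    pathway_weight_range: tuple[float, float] = (0.88, 0.999)
    background_weight_range: tuple[float, float] = (0.80, 0.87)
    decoy_modules: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pathway_size < 3:
            raise ValueError("pathway_size must be >= 3")
        if self.background_size < 0 or self.decoy_modules < 0:
            raise ValueError("sizes must be non-negative")
        if self.decoy_modules * self.pathway_size > self.background_size:
            raise ValueError("decoy modules do not fit into the background")
        for name in ("pathway_edge_prob", "background_edge_prob", "cross_edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("pathway_weight_range", "background_weight_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= MAX_SCORE):
                raise ValueError(f"{name}=({lo}, {hi}) outside (0, {MAX_SCORE}]")


def _add_er_edges(g, nodes, p, wrange, rng):
    nodes = list(nodes)
    lo, hi = wrange
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(lo, hi)))


def _add_cross_edges(g, nodes_a, nodes_b, p, wrange, rng):
    lo, hi = wrange
    for a in nodes_a:
        for b in nodes_b:
            if rng.random() < p:
                g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))


def generate(spec: SyntheticSpec) -> tuple[nx.Graph, ReferencePathway]:
    """Generate (network, planted reference pathway), deterministic per seed.

    Pathway-internal, background-internal and cross edges are drawn
    Erdős–Rényi style at the spec's probabilities, with weights uniform in
    the corresponding range; decoy modules (each of ``pathway_size`` nodes,
    carved out of the background) get pathway density at background weights.
    A repair pass then adds minimum necessary edges so the pathway induces a
    connected subgraph and the whole network is connected.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pathway = [f"PWY{i:03d}" for i in range(spec.pathway_size)]
    background = [f"BGD{i:03d}" for i in range(spec.background_size)]

    g = nx.Graph()
    g.add_nodes_from(pathway)
    g.add_nodes_from(background)

    _add_er_edges(g, pathway, spec.pathway_edge_prob, spec.pathway_weight_range, rng)

    # carve decoy modules out of the front of the background node list
    decoys = [
        background[k * spec.pathway_size:(k + 1) * spec.pathway_size]
        for k in range(spec.decoy_modules)
    ]
    for module in decoys:
        _add_er_edges(g, module, spec.pathway_edge_prob, spec.background_weight_range, rng)

    decoy_nodes = {n for module in decoys for n in module}
    plain = [n for n in background if n not in decoy_nodes]
    _add_er_edges(g, plain, spec.background_edge_prob, spec.background_weight_range, rng)
    for module in decoys:
        _add_cross_edges(
            g, module, plain, spec.background_edge_prob, spec.background_weight_range, rng
        )
    _add_cross_edges(
        g, pathway, background, spec.cross_edge_prob, spec.background_weight_range, rng
    )

    _repair_connectivity(g, pathway, spec, rng)

    return g, ReferencePathway(name="planted", members=frozenset(pathway))


def _repair_connectivity(g, pathway, spec, rng) -> None:
    """Join stray components: pathway-internal first, then the full graph."""
    lo_p, hi_p = spec.pathway_weight_range
    sub = g.subgraph(pathway)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    while len(comps) > 1:
        a = comps[0][rng.integers(len(comps[0]))]
        b = comps[1][rng.integers(len(comps[1]))]
        g.add_edge(a, b, weight=float(rng.uniform(lo_p, hi_p)))
        comps = [sorted(c) for c in nx.connected_components(g.subgraph(pathway))]

    lo_b, hi_b = spec.background_weight_range
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)
    while len(comps) > 1:
        a = comps[0][rng.integers(len(comps[0]))]
        b = comps[1][rng.integers(len(comps[1]))]
        g.add_edge(a, b, weight=float(rng.uniform(lo_b, hi_b)))
        comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)


def pick_seeds(reference: ReferencePathway, k: int, rng_seed: int) -> SeedSet:
    """A uniform random k-subset of the reference pathway as seed proteins."""
    members = sorted(reference.members)
    if not 1 <= k <= len(members):
        raise ValueError(f"k={k} outside [1, {len(members)}]")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(members, size=k, replace=False)
    return SeedSet(given=frozenset(str(s) for s in chosen))
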