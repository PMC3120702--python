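"""Evaluation of predicted networks: precision/recall and functional enrichment.

Precision is the fraction of predicted proteins that belong to the reference
pathway; recall is the fraction of the reference pathway recovered.  Enrichment
of annotation terms among the predicted proteins uses the upper-tail
hypergeometric probability

    P(X >= x) = sum_{k=x}^{min(n, M)} C(n, k) C(N - n, M - k) / C(N, M)

with N the background proteome size, n the number of background proteins
carrying the term, M the predicted network size and x the number of predicted
proteins carrying the term.  Raw p-values are reported by default; an optional
Benjamini-Hochberg column is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "ReferencePathway",
    "EnrichmentResult",
    "precision_recall",
    "percent",
    "hypergeom_pvalue",
    "enrich",
    "read_gmt",
    "read_node_list",
]


@dataclass(frozen=True)
class ReferencePathway:
    """A named reference pathway: the ground-truth protein membership."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference pathway {self.name!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation term in a predicted network."""

    term: str
    x: int
    n_annotated: int
    M: int
    N: int
    p_value: float
    p_adjusted: float | None = None


def precision_recall(
    predicted: Iterable[str], reference: ReferencePathway
) -> tuple[float, float]:
    """(precision, recall) of a predicted protein set against a reference pathway."""
    pred = set(predicted)
    if not pred:
        raise ValueError("predicted set is empty")
    hit = len(pred & reference.members)
    return hit / len(pred), hit / len(reference.members)


def percent(fraction: float) -> int:
    """Whole-percent with half-up rounding (matches figure-caption style)."""
    return int(fraction * 100 + 0.5)


def hypergeom_pvalue(x: int, n_annotated: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    Draw M proteins from a background of N containing ``n_annotated``
    annotated ones; the p-value is the probability of seeing at least ``x``
    annotated proteins in the draw.
    """
    if N < 1 or M < 0 or n_annotated < 0:
        raise ValueError("counts must be non-negative and N >= 1")
    if M > N or n_annotated > N:
        raise ValueError(f"M={M} and n={n_annotated} must not exceed N={N}")
    if not 0 <= x <= min(n_annotated, M):
        raise ValueError(f"x={x} outside [0, min(n={n_annotated}, M={M})]")
    return float(hypergeom.sf(x - 1, N, n_annotated, M))


def enrich(
    network_nodes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background_size: int,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment of every annotation term with at least one hit, by p-value.

    ``annotations`` maps term identifier to its gene set (GMT-style).  Terms
    with no overlap with the network are excluded; no multiple-testing
    correction is applied unless ``adjust=True`` adds a Benjamini-Hochberg
    column.
    """
    if not annotations:
        raise ValueError("annotations are empty")
    nodes = set(network_nodes)
    M = len(nodes)
    max_term = max(len(set(genes)) for genes in annotations.values())
    if background_size < max_term:
        raise ValueError(
            f"background size {background_size} smaller than the largest "
            f"annotation term ({max_term})"
        )
    if background_size < M:
        raise ValueError(f"background size {background_size} smaller than network ({M})")

    results = []
    for term in sorted(annotations):
        genes = set(annotations[term])
        x = len(nodes & genes)
        if x == 0:
            continue
        n = len(genes)
        results.append(
            EnrichmentResult(
                term=term,
                x=x,
                n_annotated=n,
                M=M,
                N=background_size,
                p_value=hypergeom_pvalue(x, n, M, background_size),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if adjust and results:
        adjusted = false_discovery_control([r.p_value for r in results], method="bh")
        results = [
            EnrichmentResult(
                term=r.term, x=r.x, n_annotated=r.n_annotated, M=r.M, N=r.N,
                p_value=r.p_value, p_adjusted=float(q),
            )
            for r, q in zip(results, adjusted)
        ]
    return results


def read_gmt(stream: IO[str]) -> dict[str, set[str]]:
    """Read a GMT gene-set file: ``term<TAB>description<TAB>gene1<TAB>...``."""
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        term = fields[0]
        genes = {g for g in fields[2:] if g}
        if genes:
            terms[term] = genes
    if not terms:
        raise ValueError("GMT file contains no gene sets")
    return terms


def read_node_list(stream: IO[str]) -> set[str]:
    """Read a plain node list: one identifier per line, ``#`` comments allowed."""
    nodes = set()
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if line:
            nodes.add(line)
    if not nodes:
        raise ValueError("node list is empty")
    return nodes


def write_enrichment_tsv(results: Iterable[EnrichmentResult], stream: IO[str]) -> None:
    rows = list(results)
    has_adj = any(r.p_adjusted is not None for r in rows)
    header = "term\tx\tn\tM\tN\tp_value"
    stream.write(header + ("\tp_adjusted\n" if has_adj else "\n"))
    for r in rows:
        line = f"{r.term}\t{r.x}\t{r.n_annotated}\t{r.M}\t{r.N}\t{r.p_value:.6g}"
        if has_adj:
            line += f"\t{r.p_adjusted:.6g}" if r.p_adjusted is not None else "\t"
        stream.write(line + "\n")
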