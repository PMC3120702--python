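"""Interaction-table parsing, score normalization and weighted-network construction.

Edge weights merge two confidence sources: an integrated evidence score in the
STRING style (integer 0-999 in the raw table) and a GO semantic-similarity
score in the TCSS style (real in [0, 1], accepted as a precomputed column).
Both are normalized onto [0, 0.999] and combined with a probabilistic-OR rule
so that a pair scored by only one source keeps that source's score unchanged
and the combined weight never exceeds 0.999.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import networkx as nx

__all__ = [
    "MAX_SCORE",
    "INFINITE_DISTANCE",
    "ScoredInteraction",
    "InputFormatError",
    "normalize_string_score",
    "normalize_tcss_score",
    "combine_scores",
    "read_interactions",
    "build_network",
    "to_distance",
    "write_interactions_tsv",
    "write_sif",
    "network_to_interactions",
]

logger = logging.getLogger(__name__)

#: Upper bound of normalized scores and combined edge weights.
MAX_SCORE = 0.999

#: Sentinel distance for absent edges / unreachable nodes.
INFINITE_DISTANCE = math.inf


class InputFormatError(ValueError):
    """A row or file that cannot be interpreted under the declared dialect."""


@dataclass(frozen=True)
class ScoredInteraction:
    """One undirected protein pair with its per-source and combined scores.

    ``protein_a``/``protein_b`` are opaque case-sensitive identifiers;
    ``s_tcss`` and ``s_string`` are the normalized per-source scores and
    ``combined`` the edge weight, all in [0, 0.999].
    """

    protein_a: str
    protein_b: str
    s_tcss: float
    s_string: float
    combined: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise InputFormatError(
                f"self-interaction {self.protein_a!r}-{self.protein_b!r} is not allowed"
            )
        for name in ("s_tcss", "s_string", "combined"):
            v = getattr(self, name)
            if not 0.0 <= v <= MAX_SCORE:
                raise InputFormatError(
                    f"{name}={v!r} outside [0, {MAX_SCORE}] for pair "
                    f"{self.protein_a}-{self.protein_b}"
                )

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


def normalize_string_score(raw: int) -> float:
    """Map a raw integer evidence score 0-999 onto [0, 0.999] by dividing by 1000."""
    if isinstance(raw, bool) or not isinstance(raw, int):
        raise InputFormatError(f"STRING-style score must be an integer, got {raw!r}")
    if not 0 <= raw <= 999:
        raise InputFormatError(f"STRING-style score {raw} outside [0, 999]")
    return raw / 1000.0


def normalize_tcss_score(raw: float) -> float:
    """Map a semantic-similarity score in [0, 1] onto [0, 0.999] by multiplying by 0.999."""
    if not 0.0 <= raw <= 1.0:
        raise InputFormatError(f"TCSS-style score {raw!r} outside [0, 1]")
    return raw * MAX_SCORE


def combine_scores(s_tcss: float, s_string: float) -> float:
    """Combine the two normalized scores into one edge weight.

    Probabilistic-OR on the [0, 1] rescaled scores, mapped back to the
    0.999 cap::

        combined = 0.999 * (1 - (1 - s_tcss/0.999) * (1 - s_string/0.999))

    The rule is symmetric, a zero component returns the other score
    unchanged, and the result never exceeds either bound.
    """
    for name, v in (("s_tcss", s_tcss), ("s_string", s_string)):
        if not 0.0 <= v <= MAX_SCORE:
            raise InputFormatError(f"{name}={v!r} outside [0, {MAX_SCORE}]")
    a = s_tcss / MAX_SCORE
    b = s_string / MAX_SCORE
    combined = MAX_SCORE * (1.0 - (1.0 - a) * (1.0 - b))
    # guard against float drift past the cap
    return min(combined, MAX_SCORE)


def _parse_string_v8_row(fields: list[str], lineno: int) -> ScoredInteraction | None:
    if len(fields) < 3:
        raise InputFormatError(f"line {lineno}: expected 3 columns, got {len(fields)}")
    a, b, raw = fields[0], fields[1], fields[2]
    try:
        score = int(raw)
    except ValueError:
        raise InputFormatError(
            f"line {lineno}: score {raw!r} is not an integer"
        ) from None
    if a == b:
        logger.warning("line %d: dropping self-interaction %s-%s", lineno, a, b)
        return None
    s_string = normalize_string_score(score)
    return ScoredInteraction(a, b, 0.0, s_string, combine_scores(0.0, s_string))


_GENERIC_COLUMNS = {"protein_a", "protein_b", "s_tcss", "s_string"}


def _iter_rows(stream: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t") if "\t" in line else line.split()


def read_interactions(stream: IO[str], dialect: str = "string_v8") -> list[ScoredInteraction]:
    """Parse an interaction table into deduplicated :class:`ScoredInteraction` rows.

    Parameters
    ----------
    stream:
        Text stream of the table.  ``string_v8`` dialect: three columns
        ``protein1  protein2  combined_score`` with an integer score 0-999
        (a header line starting with ``protein1`` is skipped).  ``generic``
        dialect: headered TSV with columns ``protein_a  protein_b  s_tcss
        s_string``; either score column may be blank.
    dialect:
        ``"string_v8"`` or ``"generic"``.

    Duplicate unordered pairs keep the maximum combined score.  Self-pairs
    are dropped with a warning.  Pairs with neither score are dropped.
    """
    if dialect not in ("string_v8", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")

    rows = _iter_rows(stream)
    header: dict[str, int] | None = None
    best: dict[frozenset[str], ScoredInteraction] = {}
    n_rows = 0

    for lineno, fields in rows:
        if dialect == "generic" and header is None:
            header = {name.strip(): i for i, name in enumerate(fields)}
            missing = {"protein_a", "protein_b"} - set(header)
            if missing:
                raise InputFormatError(
                    f"line {lineno}: generic header missing columns {sorted(missing)}"
                )
            continue
        if dialect == "string_v8" and n_rows == 0 and fields[0] in ("protein1", "protein_a"):
            continue
        n_rows += 1

        if dialect == "string_v8":
            inter = _parse_string_v8_row(fields, lineno)
            if inter is None:  # self-pair, already logged
                continue
        else:
            assert header is not None

            def field(col: str) -> str:
                idx = header.get(col)
                if idx is None or idx >= len(fields):
                    return ""
                return fields[idx].strip()

            a, b = field("protein_a"), field("protein_b")
            if not a or not b:
                raise InputFormatError(f"line {lineno}: missing protein identifier")
            try:
                s_tcss_raw = float(field("s_tcss")) if field("s_tcss") else 0.0
                s_string_raw = float(field("s_string")) if field("s_string") else 0.0
            except ValueError:
                raise InputFormatError(f"line {lineno}: unparseable score") from None
            # generic columns carry already-normalized values in [0, 0.999]
            for name, v in (("s_tcss", s_tcss_raw), ("s_string", s_string_raw)):
                if not 0.0 <= v <= MAX_SCORE:
                    raise InputFormatError(
                        f"line {lineno}: {name}={v} outside [0, {MAX_SCORE}]"
                    )
            if a == b:
                logger.warning("line %d: dropping self-interaction %s-%s", lineno, a, b)
                continue
            inter = ScoredInteraction(
                a, b, s_tcss_raw, s_string_raw, combine_scores(s_tcss_raw, s_string_raw)
            )

        if inter.combined == 0.0:
            continue  # neither source scored the pair
        prev = best.get(inter.pair)
        if prev is None or inter.combined > prev.combined:
            best[inter.pair] = inter

    if dialect == "string_v8" and n_rows == 0 and not best:
        raise InputFormatError("empty interaction table")
    if dialect == "generic" and header is None:
        raise InputFormatError("empty interaction table")
    return list(best.values())


def read_interactions_path(path: str, dialect: str = "string_v8") -> list[ScoredInteraction]:
    with open(path) as fh:
        try:
            return read_interactions(fh, dialect=dialect)
        except InputFormatError as exc:
            raise InputFormatError(f"{path}: {exc}") from None


def build_network(
    interactions: Iterable[ScoredInteraction],
    score_threshold: float,
    isolated_seeds: Iterable[str] = (),
) -> nx.Graph:
    """Build the thresholded weighted PPI graph.

    Edges with combined score below ``score_threshold`` are treated as absent.
    The node set is the endpoints of retained edges plus ``isolated_seeds``
    (seed proteins kept even when every one of their edges fell below the
    threshold, so downstream code can raise a clear "seed not connected"
    error instead of a KeyError).
    """
    if not 0.0 < score_threshold < 1.0:
        raise ValueError(f"score_threshold {score_threshold} outside (0, 1)")
    g = nx.Graph()
    for inter in interactions:
        if inter.combined >= score_threshold:
            g.add_edge(inter.protein_a, inter.protein_b, weight=inter.combined)
    for seed in isolated_seeds:
        g.add_node(seed)
    return g


def to_distance(w: float | None) -> float:
    """Convert an edge weight to a search distance: ``1 - w``; absent -> infinity."""
    if w is None:
        return INFINITE_DISTANCE
    return 1.0 - w


def network_to_interactions(network: nx.Graph) -> list[ScoredInteraction]:
    """View a weighted graph as generic-dialect rows (weight carried in s_tcss)."""
    out = []
    for a, b, w in network.edges(data="weight"):
        out.append(ScoredInteraction(a, b, w, 0.0, w))
    return out


def write_interactions_tsv(interactions: Iterable[ScoredInteraction], stream: IO[str]) -> None:
    """Write rows in the generic headered dialect (round-trips exactly)."""
    stream.write("protein_a\tprotein_b\ts_tcss\ts_string\n")
    for inter in sorted(interactions, key=lambda x: (x.protein_a, x.protein_b)):
        stream.write(
            f"{inter.protein_a}\t{inter.protein_b}\t"
            f"{inter.s_tcss!r}\t{inter.s_string!r}\n"
        )


def write_sif(network: nx.Graph, stream: IO[str], relation: str = "pp") -> None:
    """Write the edge list in SIF (``node1<TAB>pp<TAB>node2``) for Cytoscape."""
    for a, b in sorted(map(sorted, network.edges())):
        stream.write(f"{a}\t{relation}\t{b}\n")
    for node in sorted(nx.isolates(network)):
        stream.write(f"{node}\n")
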