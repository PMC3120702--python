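"""End-to-end orchestration: scoring -> pre-processing -> descent -> pruning -> ranking."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import evaluation, preprocess, scoring, sdm

__all__ = ["RunConfig", "ScanResult", "run_scan", "run_evaluate"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective parameters of one scan; serializes losslessly to YAML/JSON."""

    interactions: str = ""
    seeds: str = ""
    dialect: str = "generic"
    out_dir: str = "seedscan_out"
    score_threshold: float = 0.800
    credible_threshold: float = preprocess.DEFAULT_CREDIBLE_THRESHOLD
    dfs_path_length: int = preprocess.DEFAULT_PATH_LENGTH
    size_threshold: int = sdm.DEFAULT_SIZE_THRESHOLD
    keep_candidates: int = sdm.DEFAULT_KEEP
    top_n: int = sdm.DEFAULT_TOP_N
    rng_seed: int = 0
    expand_cascade: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold outside (0, 1)")
        if not 0.0 < self.credible_threshold < 1.0:
            raise ValueError("credible_threshold outside (0, 1)")
        if self.dfs_path_length < 1:
            raise ValueError("dfs_path_length must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class ScanResult:
    config: RunConfig
    seeds: preprocess.SeedSet
    trace: sdm.DescentTrace
    ranked: list[sdm.CandidateNetwork]
    final: sdm.CandidateNetwork

    def report(self) -> dict:
        """JSON-serializable run report embedding parameters, trace and networks."""
        return {
            "config": asdict(self.config),
            "seeds": {
                "given": sorted(self.seeds.given),
                "expanded": sorted(self.seeds.expanded),
                "provenance": dict(sorted(self.seeds.provenance.items())),
            },
            "trace": self.trace.to_dict(),
            "networks": [
                {
                    "rank": i + 1,
                    "size": c.size,
                    "density": c.density,
                    "avg_weight": c.avg_weight,
                    "score": c.score,
                    "nodes": sorted(c.nodes),
                    "edges": [
                        [min(u, v), max(u, v), w]
                        for u, v, w in sorted(
                            c.graph.edges(data="weight"),
                            key=lambda e: (min(e[0], e[1]), max(e[0], e[1])),
                        )
                    ],
                }
                for i, c in enumerate(self.ranked)
            ],
            "final_nodes": sorted(self.final.nodes),
        }


def run_scan(
    config: RunConfig,
    network=None,
    seeds: preprocess.SeedSet | None = None,
    write_outputs: bool = True,
) -> ScanResult:
    """Execute the full pipeline and (optionally) write the result files.

    ``network``/``seeds`` may be passed in-memory (tests, synthetic runs);
    otherwise they are read from the paths in ``config``.  Outputs: one SIF
    file per ranked network, a summary TSV of (rank, size, density,
    avg_weight, score) and a JSON run report.
    """
    if network is None:
        inters = scoring.read_interactions_path(config.interactions, dialect=config.dialect)
        with open(config.seeds) as fh:
            seeds = preprocess.read_seed_list(fh)
        network = scoring.build_network(
            inters, config.score_threshold, isolated_seeds=seeds.given
        )
    elif seeds is None:
        raise ValueError("seeds must be given when a network is passed in-memory")

    missing = sorted(s for s in seeds.given if s not in network)
    if missing:
        raise ValueError(f"seed proteins not found in the network: {missing}")
    isolated = sorted(s for s in seeds.given if network.degree[s] == 0)
    if isolated:
        raise ValueError(
            f"seed proteins have no interaction above the score threshold: {isolated}; "
            "lower the score threshold or check the identifiers"
        )

    scoped = preprocess.common_scope(network, seeds, config.dfs_path_length)
    seeds = preprocess.expand_seeds(
        scoped, seeds, config.credible_threshold, cascade=config.expand_cascade
    )

    trace, candidates = sdm.descend(
        scoped, seeds, size_threshold=config.size_threshold, keep=config.keep_candidates
    )
    pruned = [
        sdm.prune_edges(c, rng_seed=config.rng_seed + i)
        for i, c in enumerate(candidates)
    ]
    ranked = sdm.rank_networks(pruned, top_n=config.top_n)
    final = sdm.select_final(pruned)

    result = ScanResult(config=config, seeds=seeds, trace=trace, ranked=ranked, final=final)
    if write_outputs:
        _write_outputs(result)
    return result


def _write_outputs(result: ScanResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, cand in enumerate(result.ranked, start=1):
        with open(out / f"network_rank{i}.sif", "w") as fh:
            scoring.write_sif(cand.graph, fh)
    with open(out / "summary.tsv", "w") as fh:
        fh.write("rank\tsize\tdensity\tavg_weight\tscore\n")
        for i, c in enumerate(result.ranked, start=1):
            fh.write(f"{i}\t{c.size}\t{c.density:.6f}\t{c.avg_weight:.6f}\t{c.score:.6f}\n")
    with open(out / "final_nodes.txt", "w") as fh:
        fh.write("\n".join(sorted(result.final.nodes)) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d ranked networks to %s", len(result.ranked), out)


def run_evaluate(
    predicted: set[str],
    reference: evaluation.ReferencePathway,
    annotations: dict[str, set[str]] | None = None,
    background_size: int | None = None,
) -> dict:
    """Precision/recall of a predicted node set, plus optional enrichment."""
    precision, recall = evaluation.precision_recall(predicted, reference)
    report = {
        "precision": precision,
        "recall": recall,
        "precision_percent": evaluation.percent(precision),
        "recall_percent": evaluation.percent(recall),
        "n_predicted": len(set(predicted)),
        "n_reference": len(reference.members),
        "n_correct": len(set(predicted) & reference.members),
    }
    if annotations is not None:
        if background_size is None:
            raise ValueError("background_size is required for enrichment")
        report["enrichment"] = [
            asdict(r)
            for r in evaluation.enrich(predicted, annotations, background_size)
        ]
    return report
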