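"""Config-driven orchestration of the full analysis.

One flat YAML/dict config describes the primers, the round manifest
(label, polarity, fraction, FASTQ path), and the analysis thresholds;
``run_pipeline`` executes process -> enrich -> cluster -> candidates in
order, persists every intermediate table under the output directory, and
writes a JSON run report with per-round read/duplication statistics and
the candidate table.  Outputs are pure functions of (inputs, config), so
a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .candidates import build_candidate_table, candidate_frame
from .clustering import greedy_cluster
from .enrichment import enrichment_frame, rank_by_enrichment, top_n
from .readproc import RoundPool, process_fastq

__all__ = ["RoundSpec", "PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class RoundSpec:
    label: str
    polarity: str  # unselected | positive | negative
    fastq: str
    fraction: str = "bound"


@dataclass
class PipelineConfig:
    fwd_primer: str
    rev_primer: str
    rounds: list[RoundSpec]
    mismatch_frac: float = 0.05
    region_length: int = 25
    length_tol: int = 2
    cluster_identity: float = 0.8
    homolog_identity: float = 0.85
    homolog_min_count: int = 5
    parasite_min_count: int = 10
    neg_min_count: int = 1
    top_n: int = 1000
    pseudocount: float = 1.0
    annotations: Optional[dict[str, float]] = None
    config_version: int = 1

    def __post_init__(self) -> None:
        n_unselected = sum(1 for r in self.rounds if r.polarity == "unselected")
        if n_unselected != 1:
            raise ValueError(
                f"manifest must contain exactly one unselected round, found {n_unselected}"
            )
        for r in self.rounds:
            if r.polarity not in ("unselected", "positive", "negative"):
                raise ValueError(f"round {r.label}: unknown polarity {r.polarity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rounds = [RoundSpec(**r) for r in raw.pop("rounds")]
        return cls(rounds=rounds, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {k: v for k, v in self.__dict__.items() if k != "rounds"}
        raw["rounds"] = [dict(r.__dict__) for r in self.rounds]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"rounds": [], "stages": {}}

    def stage(name: str):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name: str, t0: float) -> None:
        dt = time.perf_counter() - t0
        report["stages"][name] = round(dt, 3)
        logger.info("stage %s finished in %.2fs", name, dt)

    # --- process ---------------------------------------------------------
    t0 = stage("process")
    pools: dict[str, RoundPool] = {}
    for spec in config.rounds:
        if not Path(spec.fastq).exists():
            raise PipelineError(f"stage process: FASTQ not found for round {spec.label}: {spec.fastq}")
        try:
            pool, proc = process_fastq(
                spec.fastq, spec.label, spec.polarity,  # type: ignore[arg-type]
                config.fwd_primer, config.rev_primer,
                fraction=spec.fraction,  # type: ignore[arg-type]
                mismatch_frac=config.mismatch_frac,
                target=config.region_length, tol=config.length_tol,
            )
        except Exception as exc:
            raise PipelineError(f"stage process: round {spec.label}: {exc}") from exc
        pools[spec.label] = pool
        pool.write_tsv(outdir / f"pool_{_safe(spec.label)}.tsv")
        row = proc.to_dict()
        row["n_unique"] = pool.n_unique
        report["rounds"].append(row)
    done("process", t0)

    library = next(p for p in pools.values() if p.polarity == "unselected")
    positives = [p for p in pools.values() if p.polarity == "positive"]
    negatives = [p for p in pools.values() if p.polarity == "negative"]
    if not positives:
        raise PipelineError("stage enrich: no positive rounds in manifest")

    # --- enrich ----------------------------------------------------------
    t0 = stage("enrich")
    enriched_by_round = {}
    for pool in positives:
        try:
            records = top_n(
                rank_by_enrichment(library, pool, config.pseudocount), config.top_n
            )
        except Exception as exc:
            raise PipelineError(f"stage enrich: round {pool.round_label}: {exc}") from exc
        enriched_by_round[pool.round_label] = records
        enrichment_frame(records).to_csv(
            outdir / f"enrichment_{_safe(pool.round_label)}.tsv", sep="\t", index=False
        )
    done("enrich", t0)

    # --- cluster ---------------------------------------------------------
    t0 = stage("cluster")
    clusters_by_round = {}
    for label, records in enriched_by_round.items():
        pool = pools[label]
        seq_counts = [
            (f"{config.fwd_primer}{r.sequence}{config.rev_primer}", pool.count_of(r.sequence))
            for r in records
        ]
        clusters = greedy_cluster(seq_counts, config.cluster_identity)
        clusters_by_round[label] = clusters
        pd.DataFrame(
            [
                (cl.cluster_id, cl.representative, member, ident, cl.size)
                for cl in clusters
                for member, ident in cl.members
            ],
            columns=["cluster_id", "representative", "member", "identity", "size"],
        ).to_csv(outdir / f"clusters_{_safe(label)}.tsv", sep="\t", index=False)
    done("cluster", t0)

    # --- candidates ------------------------------------------------------
    t0 = stage("candidates")
    all_rows = []
    for label, records in enriched_by_round.items():
        rows = build_candidate_table(
            records,
            clusters_by_round[label],
            negatives,
            library,
            annotations=config.annotations,
            positive_pools=positives,
            fwd_primer=config.fwd_primer,
            rev_primer=config.rev_primer,
            neg_min_count=config.neg_min_count,
            homolog_identity=config.homolog_identity,
            homolog_min_count=config.homolog_min_count,
            parasite_min_count=config.parasite_min_count,
        )
        all_rows.extend(rows)
    cand_df = candidate_frame(all_rows)
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    report["n_candidates"] = len(cand_df)
    done("candidates", t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _safe(label: str) -> str:
    return label.replace("+", "pos").replace("-", "neg")
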