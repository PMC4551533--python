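"""Fold-enrichment analysis across selection rounds.

A sequence's fold enrichment between a reference round (usually the
unselected library R0) and a target round is the ratio of its read
fractions in the two pools.  Pools of unequal sequencing depth are made
comparable by normalizing counts to relative frequencies; a sequence
absent from the reference pool is given a configurable pseudocount
(default 1 read) so its enrichment stays finite while preserving the
ordering among observed sequences.  Enrichment is computed on random
regions only — the fixed primer regions are identical across all
sequences and carry no information about selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .readproc import RoundPool

__all__ = [
    "FrequencyTable",
    "EnrichmentRecord",
    "frequency_table",
    "fold_enrichment",
    "rank_by_enrichment",
    "top_n",
    "enrichment_frame",
]


@dataclass(frozen=True)
class FrequencyTable:
    round_label: str
    freqs: dict[str, float]


@dataclass(frozen=True)
class EnrichmentRecord:
    sequence: str
    ref_round: str
    target_round: str
    f_ref: float
    f_target: float
    fold_enrichment: float
    rank: int


def frequency_table(pool: RoundPool) -> FrequencyTable:
    """Relative frequency of every sequence in a pool (counts / total reads)."""
    total = pool.total_reads
    if total < 1:
        raise ValueError("cannot compute frequencies of an empty pool")
    return FrequencyTable(pool.round_label, {r.sequence: r.count / total for r in pool.records})


def fold_enrichment(
    seq: str,
    ref: RoundPool,
    target: RoundPool,
    pseudocount: float = 1.0,
) -> float:
    """Ratio of read fractions target/reference for one random region.

    A reference count of zero is replaced by ``pseudocount`` reads.  The
    sequence must be present in the target pool — enrichment of an absent
    sequence is not defined.
    """
    c_t = target.count_of(seq)
    if c_t == 0:
        raise ValueError(f"sequence not present in target pool {target.round_label}")
    c_r = max(ref.count_of(seq), pseudocount)
    if c_r <= 0:
        raise ZeroDivisionError("zero reference count with pseudocount < 1")
    return (c_t / target.total_reads) / (c_r / ref.total_reads)


def rank_by_enrichment(
    ref: RoundPool,
    target: RoundPool,
    pseudocount: float = 1.0,
) -> list[EnrichmentRecord]:
    """One enrichment record per target-pool sequence, ranked 1..n.

    Sorted by fold enrichment descending; ties broken by higher target
    count, then lexicographically.
    """
    if ref.total_reads < 1 or target.total_reads < 1:
        raise ValueError("both pools must be non-empty")
    ref_counts = ref.counts()
    t_total = target.total_reads
    r_total = ref.total_reads
    rows = []
    for rec in target.records:
        c_r = max(ref_counts.get(rec.sequence, 0), pseudocount)
        f_t = rec.count / t_total
        f_r = c_r / r_total
        rows.append((rec.sequence, f_r, f_t, f_t / f_r, rec.count))
    rows.sort(key=lambda r: (-r[3], -r[4], r[0]))
    return [
        EnrichmentRecord(seq, ref.round_label, target.round_label, f_r, f_t, fe, rank)
        for rank, (seq, f_r, f_t, fe, _c) in enumerate(rows, start=1)
    ]


def top_n(records: list[EnrichmentRecord], n: int = 1000) -> list[EnrichmentRecord]:
    """First ``n`` records in rank order (all of them if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(records, key=lambda r: r.rank)[:n]


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sequence, r.ref_round, r.target_round, r.f_ref, r.f_target, r.fold_enrichment, r.rank)
            for r in records
        ],
        columns=["sequence", "ref_round", "target_round", "f_ref", "f_target", "fold_enrichment", "rank"],
    )
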