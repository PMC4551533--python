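"""Candidate aptamer selection: negative-pool, homolog, and parasite flags.

Enriched sequences are screened, not silently removed: each candidate row
records whether the sequence appears in any counter-selection (negative)
pool, which abundant library sequences it is homologous to (identity
strictly above a threshold against library sequences at or above a count
floor), and whether it behaves parasitically (abundant in positive and
negative pools alike).  External binding-potential Z-scores can be joined
as a passive annotation column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .clustering import Cluster, global_identity
from .enrichment import EnrichmentRecord
from .readproc import RoundPool

__all__ = [
    "CandidateAptamer",
    "in_negative_pools",
    "library_homologs",
    "flag_parasites",
    "build_candidate_table",
    "candidate_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateAptamer:
    id: str
    sequence: str
    round: str
    rank: int
    enrichment: float
    cluster_size: Optional[int]
    in_negative_pool: bool
    library_homologs: tuple[tuple[str, float, int], ...]
    is_parasite: bool = False
    z_score: Optional[float] = None

    @property
    def is_clean(self) -> bool:
        return not self.in_negative_pool and not self.library_homologs and not self.is_parasite


def in_negative_pools(
    seq: str, negative_pools: Sequence[RoundPool], min_count: int = 1
) -> bool:
    """True iff the sequence reaches ``min_count`` reads in any negative pool."""
    for pool in negative_pools:
        if pool.polarity != "negative":
            raise ValueError(f"pool {pool.round_label} is not a negative pool")
    return any(pool.count_of(seq) >= min_count for pool in negative_pools)


def library_homologs(
    seq: str,
    library: RoundPool,
    identity_threshold: float = 0.85,
    min_count: int = 5,
) -> list[tuple[str, float, int]]:
    """Abundant library sequences homologous to ``seq``.

    Returns (library sequence, identity, library count) for every library
    sequence at >= ``min_count`` reads whose global alignment identity to
    ``seq`` is strictly greater than ``identity_threshold``.  An empty list
    means the candidate has no homologs in the unselected library.
    """
    hits = []
    for rec in library.records:
        if rec.count < min_count:
            break  # records are count-sorted
        ident = global_identity(seq, rec.sequence)
        if ident > identity_threshold:
            hits.append((rec.sequence, ident, rec.count))
    hits.sort(key=lambda h: (-h[1], -h[2], h[0]))
    return hits


def flag_parasites(
    positive_pools: Sequence[RoundPool],
    negative_pools: Sequence[RoundPool],
    min_count: int = 10,
) -> set[str]:
    """Sequences abundant in at least one positive AND one negative pool.

    Such sequences persist through counter-selection, indicating they are
    carried by amplification or collection artifacts rather than target
    binding.
    """
    if not positive_pools or not negative_pools:
        return set()
    pos_hits: set[str] = set()
    for pool in positive_pools:
        pos_hits.update(r.sequence for r in pool.records if r.count >= min_count)
    parasites: set[str] = set()
    for pool in negative_pools:
        for rec in pool.records:
            if rec.count >= min_count and rec.sequence in pos_hits:
                parasites.add(rec.sequence)
    return parasites


def build_candidate_table(
    enrichments: Sequence[EnrichmentRecord],
    clusters: Sequence[Cluster],
    negative_pools: Sequence[RoundPool],
    library: RoundPool,
    annotations: Optional[Mapping[str, float]] = None,
    positive_pools: Sequence[RoundPool] = (),
    fwd_primer: str = "",
    rev_primer: str = "",
    neg_min_count: int = 1,
    homolog_identity: float = 0.85,
    homolog_min_count: int = 5,
    parasite_min_count: int = 10,
) -> list[CandidateAptamer]:
    """Assemble the per-candidate report rows, ordered by (round, rank).

    ``clusters`` are expected to have been built on primer-attached
    sequences; pass the primers so cluster membership can be looked up.
    Homolog comparison runs on the bare random regions.  Sequences that
    never reached the clustering input get a missing cluster size and a
    logged warning.  Parasite and negative-pool hits are marked, never
    dropped.
    """
    annotations = annotations or {}
    parasites = flag_parasites(positive_pools, negative_pools, parasite_min_count)

    member_sizes: dict[str, int] = {}
    for cl in clusters:
        for member, _ident in cl.members:
            member_sizes[member] = cl.size

    rows: list[CandidateAptamer] = []
    for rec in sorted(enrichments, key=lambda r: (r.target_round, r.rank)):
        full = f"{fwd_primer}{rec.sequence}{rev_primer}"
        size = member_sizes.get(full, member_sizes.get(rec.sequence))
        if size is None:
            logger.warning(
                "sequence %s (round %s rank %d) absent from clustering input; "
                "cluster size recorded as missing",
                rec.sequence, rec.target_round, rec.rank,
            )
        rows.append(
            CandidateAptamer(
                id=f"{rec.target_round}_r{rec.rank}",
                sequence=rec.sequence,
                round=rec.target_round,
                rank=rec.rank,
                enrichment=rec.fold_enrichment,
                cluster_size=size,
                in_negative_pool=in_negative_pools(rec.sequence, negative_pools, neg_min_count),
                library_homologs=tuple(
                    library_homologs(rec.sequence, library, homolog_identity, homolog_min_count)
                ),
                is_parasite=rec.sequence in parasites,
                z_score=annotations.get(rec.sequence),
            )
        )
    if not rows:
        logger.warning("candidate table is empty")
    return rows


def candidate_frame(rows: Iterable[CandidateAptamer]) -> pd.DataFrame:
    """Tabular report mirroring the candidate-summary layout."""
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "round": c.round,
                "rank": c.rank,
                "enrichment": c.enrichment,
                "sequence": c.sequence,
                "z_score": c.z_score,
                "cluster_size": c.cluster_size,
                "in_negative_pool": c.in_negative_pool,
                "n_library_homologs": len(c.library_homologs),
                "is_parasite": c.is_parasite,
            }
            for c in rows
        ]
    )
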