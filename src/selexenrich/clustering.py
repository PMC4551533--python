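"""Greedy identity-threshold clustering of enriched sequences.

Sequences (with primers re-attached) are scanned in count-descending
order.  The first sequence seeds cluster 1; each subsequent sequence is
aligned against every existing cluster representative and joins the
cluster of highest identity when that identity reaches the threshold
(default 0.8), otherwise it seeds a new cluster.  Identity is computed
from an optimal global (end-to-end) alignment: matched columns divided by
total alignment columns, gap columns included in the denominator.

The alignment is an exact Needleman-Wunsch DP under a simple scoring
scheme (match +1, mismatch -1, gap -2, linear).  Ties among co-optimal
alignments are broken deterministically: maximize matches, then minimize
gap columns.  The DP tracks the lexicographic objective
(score, matches, -gaps) via an integer encoding and is JIT-compiled, so
all-pairs comparison of a thousand ~65-mers stays fast without the
word-filter heuristics of tools like CD-HIT-EST.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numba import njit

__all__ = [
    "AlignmentStats",
    "Cluster",
    "global_identity",
    "align_stats",
    "greedy_cluster",
    "cluster_size_of",
]

# Encoding weights for the lexicographic objective (score, matches, -gaps).
# Bounds for sequences up to ~500 nt: |gaps| <= 1024 < _M, and
# |matches*_M - gaps| < _S, so a single int64 compares lexicographically.
_M = 1 << 11
_S = 1 << 24

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


@njit(cache=True)
def _nw_kernel(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    la = a.size
    lb = b.size
    gap_step = gap * _S - 1  # one gap column: score += gap, gaps += 1

    enc_prev = np.empty(lb + 1, np.int64)
    mat_prev = np.zeros(lb + 1, np.int64)
    gap_prev = np.empty(lb + 1, np.int64)
    enc_cur = np.empty(lb + 1, np.int64)
    mat_cur = np.zeros(lb + 1, np.int64)
    gap_cur = np.empty(lb + 1, np.int64)

    for j in range(lb + 1):
        enc_prev[j] = j * gap_step
        gap_prev[j] = j

    for i in range(1, la + 1):
        enc_cur[0] = i * gap_step
        mat_cur[0] = 0
        gap_cur[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1] and ai < 4:
                d = enc_prev[j - 1] + match * _S + _M
                dm = mat_prev[j - 1] + 1
            else:
                d = enc_prev[j - 1] + mismatch * _S
                dm = mat_prev[j - 1]
            dg = gap_prev[j - 1]

            best = d
            bm = dm
            bg = dg

            u = enc_prev[j] + gap_step
            if u > best:
                best = u
                bm = mat_prev[j]
                bg = gap_prev[j] + 1

            l = enc_cur[j - 1] + gap_step
            if l > best:
                best = l
                bm = mat_cur[j - 1]
                bg = gap_cur[j - 1] + 1

            enc_cur[j] = best
            mat_cur[j] = bm
            gap_cur[j] = bg

        enc_prev, enc_cur = enc_cur, enc_prev
        mat_prev, mat_cur = mat_cur, mat_prev
        gap_prev, gap_cur = gap_cur, gap_prev

    matches = mat_prev[lb]
    gaps = gap_prev[lb]
    score = (enc_prev[lb] + gaps - matches * _M) // _S
    return score, matches, gaps


class AlignmentStats(NamedTuple):
    identity: float
    matches: int
    columns: int
    gaps: int
    score: int


def align_stats(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> AlignmentStats:
    """Optimal global alignment statistics for two sequences.

    Among score-optimal alignments the one maximizing matches and, among
    those, minimizing gap columns is reported.  N never matches anything.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    score, matches, gaps = _nw_kernel(_encode(a), _encode(b), match, mismatch, gap)
    columns = (len(a) + len(b) + gaps) // 2
    return AlignmentStats(matches / columns, int(matches), int(columns), int(gaps), int(score))


def global_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> float:
    """Alignment identity in [0, 1]: matched columns / alignment columns."""
    return align_stats(a, b, match, mismatch, gap).identity


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[tuple[str, float]]  # (sequence, identity to representative)

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(
    seq_counts: Iterable[tuple[str, int]],
    threshold: float = 0.8,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Input pairs (sequence, count) are processed in count-descending order
    (ties lexicographic).  Each sequence is compared to all existing
    representatives; it joins the highest-identity cluster if that
    identity >= threshold (ties: lowest cluster id), else founds a new
    cluster whose representative it becomes.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(seq_counts, key=lambda sc: (-sc[1], sc[0]))
    clusters: list[Cluster] = []
    for seq, _count in ordered:
        best_id = -1
        best_ident = -1.0
        for cl in clusters:
            ident = global_identity(seq, cl.representative)
            if ident > best_ident:
                best_ident = ident
                best_id = cl.cluster_id
        if best_id >= 0 and best_ident >= threshold:
            clusters[best_id - 1].members.append((seq, best_ident))
        else:
            clusters.append(Cluster(len(clusters) + 1, seq, [(seq, 1.0)]))
    return clusters


def cluster_size_of(seq: str, clusters: Sequence[Cluster]) -> int:
    """Size of the cluster containing ``seq``; KeyError if unassigned."""
    for cl in clusters:
        for member, _ident in cl.members:
            if member == seq:
                return cl.size
    raise KeyError(f"sequence not assigned to any cluster: {seq}")
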