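"""Independent reference implementations used only by the tests.

Kept deliberately separate from the package code paths they check:
a pure-Python tuple-DP global aligner, a brute-force greedy clustering
scan built on it, and a numerical mass-action equilibrium solver.
"""

from __future__ import annotations

from scipy.optimize import brentq


def nw_oracle(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Exhaustive global-alignment DP maximizing (score, matches, -gaps)
    lexicographically.  Returns (score, matches, gaps, columns)."""
    la, lb = len(a), len(b)
    NEG = (-(10**9), 0, 0)
    prev = [(j * gap, 0, -j) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [(i * gap, 0, -i)] + [NEG] * lb
        for j in range(1, lb + 1):
            ai, bj = a[i - 1], b[j - 1]
            is_match = ai == bj and ai != "N"
            ps, pm, pg = prev[j - 1]
            diag = (ps + (match if is_match else mismatch), pm + (1 if is_match else 0), pg)
            us, um, ug = prev[j]
            up = (us + gap, um, ug - 1)
            ls, lm, lg = cur[j - 1]
            left = (ls + gap, lm, lg - 1)
            cur[j] = max(diag, up, left)
        prev = cur
    score, matches, neg_gaps = prev[lb]
    gaps = -neg_gaps
    columns = (la + lb + gaps) // 2
    return score, matches, gaps, columns


def identity_oracle(a: str, b: str) -> float:
    _score, matches, _gaps, columns = nw_oracle(a, b)
    return matches / columns


def greedy_cluster_oracle(seq_counts, threshold: float = 0.8):
    """Direct transcription of the greedy scan: list of lists of sequences."""
    ordered = sorted(seq_counts, key=lambda sc: (-sc[1], sc[0]))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for seq, _count in ordered:
        best_i, best_ident = -1, -1.0
        for i, rep in enumerate(reps):
            ident = identity_oracle(seq, rep)
            if ident > best_ident:
                best_i, best_ident = i, ident
        if best_i >= 0 and best_ident >= threshold:
            clusters[best_i].append(seq)
        else:
            reps.append(seq)
            clusters.append([seq])
    return clusters


def mass_action_complex(A: float, T: float, Kd: float) -> float:
    """Numerical equilibrium [AT]: solve (A-x)(T-x) = Kd*x on [0, min(A,T)]."""
    if A == 0 or T == 0:
        return 0.0
    f = lambda x: (A - x) * (T - x) - Kd * x
    hi = min(A, T)
    if f(hi) >= 0:  # root at the boundary within round-off
        return hi
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14)
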