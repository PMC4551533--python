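from __future__ import annotations

import numpy as np
import pytest

from selexenrich import study
from selexenrich.readproc import RoundPool
from selexenrich.simdata import SimConfig, simulate_selex


@pytest.fixture(scope="session")
def primers() -> tuple[str, str]:
    return study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE


def make_pool(counts: dict[str, int], label: str = "R1", polarity: str = "positive",
              fraction: str = "bound") -> RoundPool:
    return RoundPool.from_counts(counts, label, polarity, fraction)


@pytest.fixture(scope="session")
def selex_run():
    """One shared 3-round selection at the study conditions: depth 1e5 per
    round, planted 8-nt motif, 5 parasites, adaptor contamination, negative
    pools branching at rounds 1 and 2."""
    config = SimConfig(seed=20260926, n_rounds=3, depth_per_round=100_000,
                       negative_rounds=(1, 2))
    return simulate_selex(config)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Substitute exactly n_sub positions (to a different base)."""
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)
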