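"""Synthetic CE-SELEX simulator with known ground truth.

The generator emulates the observable signatures of a multi-round aptamer
selection against a tagged protein target:

* a "random" library with a mild thymine synthesis bias, in which a small
  fraction of sequences happen to contain a binding motif and therefore
  have high affinity (low K_d) for the target;
* parasitic sequences that are carried through every round by
  amplification/collection artifacts rather than binding, so they become
  abundant in positive and negative pools alike;
* contamination of every sequencing run by an Illumina-adaptor-derived
  sequence at a constant fraction of reads, which therefore tops the
  library pool but shows fold enrichment near 1;
* round-to-round selection modeled as multinomial resampling with
  per-sequence capture weights
      w = capture_efficiency * bound_fraction(Kd_eff, [protein]) + carryover
  where the bound fraction comes from the quadratic mass-action model and
  Kd_eff is the sequence's K_d in positive rounds but the background K_d
  for planted binders in negative (counter-selection) rounds; parasites
  instead use carryover * parasite_pcr_gain in every round.

Positive rounds chain (the output of round k is the input of round k+1);
each negative round is sequenced as a side branch off the current pool.
Everything is reproducible bit-for-bit from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import study
from .binding import complex_concentration, isotherm_signal, BindingMeasurement
from .readproc import RoundPool

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SelexRun",
    "make_library",
    "simulate_round",
    "simulate_selex",
    "write_round_fastq",
    "simulate_binding_assay",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated selection.

    Defaults mirror the modeled experiment where it states a value (25-nt
    random region, five positive rounds at 50/10/5/1/0.5 nM target with
    negative rounds branching at rounds 2 and 3, thymine-biased library,
    adaptor contamination); remaining rates are fixed at values chosen to
    be realistic for CE-based selection (see the package methods note).
    """

    seed: int = 0
    n_rounds: int = 5
    depth_per_round: int = 100_000
    region_length: int = 25
    base_probs: tuple[float, float, float, float] = (0.24, 0.22, 0.22, 0.32)  # A C G T
    motif: str = "TGGTTGGT"
    max_mismatches: int = 1
    Kd_motif: float = 10.0  # nM
    Kd_bg: float = 1e5  # nM, nonspecific background binding
    protein_conc_schedule: tuple[float, ...] = study.PROTEIN_CONC_SCHEDULE_NM
    negative_protein_conc: float = 50.0  # nM GST in counter-selection
    dna_conc: float = 10.0  # nM, aptamer side of the binding quadratic
    capture_efficiency: float = 0.3
    background_carryover: float = 1e-4
    parasite_count: int = 5
    parasite_init_frac: float = 1e-3  # library frequency of each parasite
    parasite_pcr_gain: float = 1000.0
    adaptor_fraction: float = 0.02  # of reads in every sequencing run
    negative_rounds: tuple[int, ...] = (2, 3)  # 1-based round indices

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if any(p < 0 or p > 1 for p in self.base_probs):
            raise ValueError("base_probs must lie in [0, 1]")
        if self.Kd_motif <= 0 or self.Kd_bg <= 0:
            raise ValueError("Kd values must be > 0")
        if self.depth_per_round < 1:
            raise ValueError("depth_per_round must be >= 1")
        if len(self.motif) > self.region_length:
            raise ValueError("motif longer than the random region")
        if len(self.protein_conc_schedule) < self.n_rounds:
            raise ValueError("protein_conc_schedule shorter than n_rounds")

    @property
    def adaptor_sequence(self) -> str:
        return study.ILLUMINA_ADAPTOR[: self.region_length]


@dataclass
class GroundTruth:
    """Per-sequence truth labels: K_d, motif status, parasite status."""

    entries: dict[str, tuple[float, bool, bool]] = field(default_factory=dict)

    def kd(self, seq: str) -> float:
        return self.entries[seq][0]

    def is_motif(self, seq: str) -> bool:
        return self.entries[seq][1]

    def is_parasite(self, seq: str) -> bool:
        return self.entries[seq][2]

    @property
    def motif_sequences(self) -> set[str]:
        return {s for s, (_k, m, _p) in self.entries.items() if m}

    @property
    def parasite_sequences(self) -> set[str]:
        return {s for s, (_k, _m, p) in self.entries.items() if p}


def _contains_motif(matrix: np.ndarray, motif: str, max_mismatches: int) -> np.ndarray:
    """Boolean per row: does the motif occur with <= max_mismatches?"""
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    n, L = matrix.shape
    hit = np.zeros(n, dtype=bool)
    for off in range(L - m.size + 1):
        window = matrix[:, off : off + m.size]
        hit |= (window != m).sum(axis=1) <= max_mismatches
    return hit


def _rows_to_strings(matrix: np.ndarray) -> list[str]:
    return matrix.view(f"S{matrix.shape[1]}").ravel().astype(str).tolist()


def _random_regions(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    idx = rng.choice(4, size=(n, config.region_length), p=np.asarray(config.base_probs))
    return _BASES[idx]


def make_library(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[RoundPool, GroundTruth]:
    """Draw the unselected library pool (round R0) and its ground truth.

    Reads are i.i.d. draws over the per-position base probabilities, with
    parasites spiked at ``parasite_init_frac`` each and the adaptor-derived
    contaminant at ``adaptor_fraction`` of the sequencing depth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    depth = config.depth_per_round
    n_adaptor = int(round(config.adaptor_fraction * depth))
    n_per_parasite = int(round(config.parasite_init_frac * depth))
    n_random = depth - n_adaptor - config.parasite_count * n_per_parasite
    if n_random < 0:
        raise ValueError("spike fractions exceed sequencing depth")

    matrix = _random_regions(rng, n_random, config)
    has_motif = _contains_motif(matrix, config.motif, config.max_mismatches)
    seqs = _rows_to_strings(matrix)

    truth = GroundTruth()
    counts: dict[str, int] = {}
    for seq, m in zip(seqs, has_motif):
        counts[seq] = counts.get(seq, 0) + 1
        if seq not in truth.entries:
            truth.entries[seq] = (config.Kd_motif if m else config.Kd_bg, bool(m), False)

    # Parasites: random sequences guaranteed motif-free so their abundance
    # trajectory is driven purely by the amplification artifact.
    n_parasites = 0
    while n_parasites < config.parasite_count:
        cand_mat = _random_regions(rng, 1, config)
        if _contains_motif(cand_mat, config.motif, config.max_mismatches)[0]:
            continue
        seq = _rows_to_strings(cand_mat)[0]
        if seq in truth.entries:
            continue
        truth.entries[seq] = (config.Kd_bg, False, True)
        counts[seq] = counts.get(seq, 0) + n_per_parasite
        n_parasites += 1

    adaptor = config.adaptor_sequence
    if n_adaptor:
        counts[adaptor] = counts.get(adaptor, 0) + n_adaptor
    if adaptor not in truth.entries:
        truth.entries[adaptor] = (config.Kd_bg, False, False)

    pool = RoundPool.from_counts(counts, "R0", "unselected", "free")
    return pool, truth


def _capture_weights(
    pool: RoundPool,
    truth: GroundTruth,
    protein_conc: float,
    is_negative: bool,
    config: SimConfig,
) -> np.ndarray:
    kds = np.empty(pool.n_unique)
    parasite = np.zeros(pool.n_unique, dtype=bool)
    for i, rec in enumerate(pool.records):
        kd, is_motif, is_par = truth.entries.get(rec.sequence, (config.Kd_bg, False, False))
        parasite[i] = is_par
        if is_negative and is_motif:
            kd = config.Kd_bg  # planted binders have no affinity for the tag
        kds[i] = kd
    A = config.dna_conc
    bound = complex_concentration(A, protein_conc, kds) / A if protein_conc > 0 else np.zeros_like(kds)
    w = config.capture_efficiency * np.asarray(bound) + config.background_carryover
    w[parasite] = config.background_carryover * config.parasite_pcr_gain
    return w


def simulate_round(
    pool: RoundPool,
    truth: GroundTruth,
    protein_conc: float,
    is_negative: bool,
    config: SimConfig,
    rng: np.random.Generator,
    round_label: str = "R?",
) -> RoundPool:
    """One selection round: weight, multinomially resample, contaminate.

    The next pool is a multinomial sample of ``depth_per_round`` reads from
    the count-weighted capture probabilities, with the adaptor contaminant
    re-injected at sequencing time at ``adaptor_fraction`` of the depth.
    """
    if pool.total_reads < 1:
        raise ValueError("cannot select from an empty pool")
    w = _capture_weights(pool, truth, protein_conc, is_negative, config)
    counts = np.array([r.count for r in pool.records], dtype=float)
    mass = counts * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("all capture weights are zero; nothing to select")

    depth = config.depth_per_round
    n_adaptor = int(round(config.adaptor_fraction * depth))
    sampled = rng.multinomial(depth - n_adaptor, mass / total)

    new_counts = {
        pool.records[i].sequence: int(c) for i, c in enumerate(sampled) if c > 0
    }
    if n_adaptor:
        adaptor = config.adaptor_sequence
        new_counts[adaptor] = new_counts.get(adaptor, 0) + n_adaptor
    return RoundPool.from_counts(
        new_counts, round_label, "negative" if is_negative else "positive", "bound"
    )


@dataclass
class SelexRun:
    """All pools of one simulated selection plus the ground truth."""

    config: SimConfig
    library: RoundPool
    positives: list[RoundPool]
    negatives: dict[str, RoundPool]
    truth: GroundTruth

    @property
    def final_round(self) -> RoundPool:
        return self.positives[-1]

    def all_pools(self) -> list[RoundPool]:
        return [self.library, *self.positives, *self.negatives.values()]


def simulate_selex(config: SimConfig) -> SelexRun:
    """Run the full simulated selection: library, positive chain, negatives."""
    rng = np.random.default_rng(config.seed)
    library, truth = make_library(config, rng)
    pool = library
    positives: list[RoundPool] = []
    negatives: dict[str, RoundPool] = {}
    for k in range(1, config.n_rounds + 1):
        pool = simulate_round(
            pool, truth, config.protein_conc_schedule[k - 1], False, config, rng,
            round_label=f"R{k}",
        )
        positives.append(pool)
        if k in config.negative_rounds:
            label = f"R{k}-"
            negatives[label] = simulate_round(
                pool, truth, config.negative_protein_conc, True, config, rng,
                round_label=label,
            )
    return SelexRun(config, library, positives, negatives, truth)


def write_round_fastq(
    pool: RoundPool,
    fwd_primer: str,
    rev_primer: str,
    adaptor: str,
    path: str | Path,
) -> None:
    """Emit a pool as FASTQ: each read count times as fwd+region+rev+adaptor.

    Quality is constant ('I'); the processing pipeline ignores it.  The
    file round-trips exactly through the read-processing stage.
    """
    with open(path, "wt") as fh:
        n = 0
        for rec in pool.records:
            read = f"{fwd_primer}{rec.sequence}{rev_primer}{adaptor}"
            qual = "I" * len(read)
            for _ in range(rec.count):
                fh.write(f"@{pool.round_label}_{n}\n{read}\n+\n{qual}\n")
                n += 1


def simulate_binding_assay(
    Kd: float,
    A: float,
    constant: float,
    T_grid: Sequence[float],
    noise_sd: float = 0.02,
    replicates: int = 2,
    seed: int | np.random.Generator = 0,
) -> list[BindingMeasurement]:
    """Noisy titration data from the quadratic isotherm.

    Gaussian noise with standard deviation ``noise_sd * constant`` is added
    independently to every point; ``replicates`` full titrations are drawn.
    """
    if Kd <= 0 or A <= 0 or constant <= 0:
        raise ValueError("Kd, A and constant must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = np.asarray(T_grid, dtype=float)
    clean = isotherm_signal(T, A, Kd, constant)
    out: list[BindingMeasurement] = []
    for rep in range(1, replicates + 1):
        noisy = clean + rng.normal(0.0, noise_sd * constant, size=T.size)
        out.extend(BindingMeasurement(float(t), float(s), rep) for t, s in zip(T, noisy))
    return out
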