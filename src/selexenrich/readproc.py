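"""FASTQ read processing for SELEX pools.

Raw per-round FASTQ reads are amplicons of the form

    forward primer + random region (~25 nt) + reverse-primer site + adaptor

Processing removes both primers (substitutions tolerated up to a fraction
of the primer length, indels forbidden), discards everything downstream of
the reverse-primer site, keeps regions within a length window, and
collapses the surviving random regions into a deduplicated count table
(one record per distinct sequence, sorted by count descending).
"""

from __future__ import annotations

import gzip
import io
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FastqParseError",
    "RawRead",
    "TrimResult",
    "PoolRecord",
    "RoundPool",
    "read_fastq",
    "trim_primers",
    "filter_length",
    "dedup_counts",
    "duplication_percent",
    "process_fastq",
    "ProcessingReport",
]

Polarity = Literal["unselected", "positive", "negative"]
Fraction = Literal["bound", "free"]
TrimStatus = Literal["ok", "no_forward_primer", "no_reverse_primer", "bad_length"]


class FastqParseError(ValueError):
    """Raised when a FASTQ file is malformed; names the offending record index."""


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record.  Quality is carried but never used downstream."""

    read_id: str
    bases: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("read has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError("quality length differs from sequence length")


@dataclass(frozen=True)
class TrimResult:
    status: TrimStatus
    random_region: Optional[str] = None


@dataclass(frozen=True)
class PoolRecord:
    sequence: str
    count: int


@dataclass
class RoundPool:
    """Deduplicated sequence/count table for one selection round.

    Records are unique by sequence and kept sorted by count descending,
    ties broken lexicographically.
    """

    round_label: str
    polarity: Polarity
    fraction: Fraction
    records: list[PoolRecord] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        return {r.sequence: r.count for r in self.records}

    def count_of(self, sequence: str) -> int:
        return self.counts().get(sequence, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": [r.sequence for r in self.records],
             "count": [r.count for r in self.records]}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        round_label: str,
        polarity: Polarity,
        fraction: Fraction = "bound",
    ) -> "RoundPool":
        records = [
            PoolRecord(seq, int(c))
            for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if c > 0
        ]
        return cls(round_label, polarity, fraction, records)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        round_label: str,
        polarity: Polarity,
        fraction: Fraction = "bound",
    ) -> "RoundPool":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": int})
        return cls.from_counts(dict(zip(df["sequence"], df["count"])), round_label, polarity, fraction)


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Yield every record of a (plain or gzipped) FASTQ file in file order.

    Malformed records raise :class:`FastqParseError` naming the 0-based
    record index.
    """
    with _open_maybe_gzip(path) as handle:
        index = 0
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            quality = "".join(
                chr(q + 33) for q in rec.letter_annotations.get("phred_quality", [])
            ) or None
            try:
                yield RawRead(rec.id, str(rec.seq).upper(), quality)
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            index += 1


def _mismatches_within(a: str, b: str, start: int, budget: int) -> bool:
    """True iff a[start:start+len(b)] differs from b at <= budget positions.

    N never matches anything (counts as a mismatch).
    """
    n = 0
    for i, ch in enumerate(b):
        c = a[start + i]
        if c != ch or c == "N":
            n += 1
            if n > budget:
                return False
    return True


def trim_primers(
    read: RawRead | str,
    fwd: str,
    rev: str,
    mismatch_frac: float = 0.05,
    target: int = 25,
    tol: int = 2,
) -> TrimResult:
    """Locate both primers and extract the random region between them.

    The forward primer is anchored at position 0 (the reads are amplicons);
    the reverse primer is scanned left to right after the forward primer and
    the leftmost acceptable hit wins.  Each primer tolerates up to
    ``floor(mismatch_frac * len(primer))`` substitutions and no indels;
    everything from the reverse primer onward (adaptors included) is
    discarded.  Regions outside ``target +/- tol`` yield status
    ``bad_length``.
    """
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    if not 0 <= mismatch_frac < 0.5:
        raise ValueError("mismatch_frac must be in [0, 0.5)")
    bases = read.bases if isinstance(read, RawRead) else read

    fwd_budget = math.floor(mismatch_frac * len(fwd))
    rev_budget = math.floor(mismatch_frac * len(rev))

    if len(bases) < len(fwd) or not _mismatches_within(bases, fwd, 0, fwd_budget):
        return TrimResult("no_forward_primer")

    start = len(fwd)
    hit = -1
    for j in range(start, len(bases) - len(rev) + 1):
        if _mismatches_within(bases, rev, j, rev_budget):
            hit = j
            break
    if hit < 0:
        return TrimResult("no_reverse_primer")

    region = bases[start:hit]
    if not filter_length(region, target, tol):
        return TrimResult("bad_length")
    return TrimResult("ok", region)


def filter_length(region: str, target: int = 25, tol: int = 2) -> bool:
    """True iff the region length lies in the window ``target +/- tol``."""
    return target - tol <= len(region) <= target + tol


def dedup_counts(
    regions: Iterable[str],
    round_label: str,
    polarity: Polarity,
    fraction: Fraction = "bound",
) -> RoundPool:
    """Collapse trimmed regions into one record per distinct sequence."""
    return RoundPool.from_counts(dict(Counter(regions)), round_label, polarity, fraction)


def duplication_percent(
    pool: RoundPool,
    mode: Literal["fraction_of_total", "relative_to_unique"] = "fraction_of_total",
) -> float:
    """Percent sequence duplication of a pool.

    ``fraction_of_total`` (default, FastQC-like):
        100 * (total - unique) / total
    ``relative_to_unique`` (duplicates relative to unique sequences):
        100 * (total - unique) / unique
    """
    total = pool.total_reads
    if total < 1:
        raise ValueError("duplication undefined for an empty pool")
    dups = total - pool.n_unique
    if mode == "fraction_of_total":
        return 100.0 * dups / total
    if mode == "relative_to_unique":
        return 100.0 * dups / pool.n_unique
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ProcessingReport:
    round_label: str
    reads_in: int
    reads_accepted: int
    n_no_forward_primer: int
    n_no_reverse_primer: int
    n_bad_length: int
    duplication_pct: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def process_fastq(
    path: str | Path,
    round_label: str,
    polarity: Polarity,
    fwd: str,
    rev: str,
    fraction: Fraction = "bound",
    mismatch_frac: float = 0.05,
    target: int = 25,
    tol: int = 2,
) -> tuple[RoundPool, ProcessingReport]:
    """Run the full per-round pipeline: parse, trim, length-filter, dedup."""
    tallies = {"ok": 0, "no_forward_primer": 0, "no_reverse_primer": 0, "bad_length": 0}
    regions: list[str] = []
    for read in read_fastq(path):
        res = trim_primers(read, fwd, rev, mismatch_frac, target, tol)
        tallies[res.status] += 1
        if res.status == "ok":
            regions.append(res.random_region)  # type: ignore[arg-type]
    pool = dedup_counts(regions, round_label, polarity, fraction)
    dup = duplication_percent(pool) if pool.total_reads else 0.0
    report = ProcessingReport(
        round_label=round_label,
        reads_in=sum(tallies.values()),
        reads_accepted=tallies["ok"],
        n_no_forward_primer=tallies["no_forward_primer"],
        n_no_reverse_primer=tallies["no_reverse_primer"],
        n_bad_length=tallies["bad_length"],
        duplication_pct=dup,
    )
    return pool, report
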