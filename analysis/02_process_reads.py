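#!/usr/bin/env python
"""Process the raw FASTQ pools: trim primers, length-filter, deduplicate.

Reads results/sim/*.fastq, writes one count table per round plus a
sequencing-summary table (reads in/accepted, unique sequences, percent
duplication) under results/pools/.  The duplication column shows the
selection signature: low in the unselected library, growing over rounds.
"""

from pathlib import Path

import pandas as pd

from selexenrich import study
from selexenrich.readproc import process_fastq

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results" / "pools"


def round_meta(name: str) -> tuple[str, str, str]:
    label = name.replace("neg", "-")
    if label == "R0":
        return label, "unselected", "free"
    return label, ("negative" if label.endswith("-") else "positive"), "bound"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sorted(SIM.glob("*.fastq")):
        label, polarity, fraction = round_meta(path.stem)
        pool, report = process_fastq(path, label, polarity,
                                     study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE,
                                     fraction=fraction)
        pool.write_tsv(OUT / f"{path.stem}.tsv")
        rows.append({**report.to_dict(), "polarity": polarity, "n_unique": pool.n_unique})
        print(f"{label}: {report.reads_accepted}/{report.reads_in} reads accepted, "
              f"{pool.n_unique} unique, duplication {report.duplication_pct:.1f}%")
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "sequencing_summary.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'sequencing_summary.tsv'}")


if __name__ == "__main__":
    main()
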