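#!/usr/bin/env python
"""Rank every sequence in each positive round by fold enrichment over R0.

Reads the count tables from results/pools/, writes per-round enrichment
tables (sequence, frequencies, fold enrichment, rank) to
results/enrichment/, and reports how many of the most enriched sequences
are planted binders according to the simulation ground truth.
"""

from pathlib import Path

import pandas as pd

from selexenrich.enrichment import enrichment_frame, rank_by_enrichment, top_n
from selexenrich.readproc import RoundPool

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    library = RoundPool.read_tsv(BASE / "pools" / "R0.tsv", "R0", "unselected", "free")
    truth = pd.read_csv(BASE / "sim" / "ground_truth.tsv", sep="\t")
    binders = set(truth.loc[truth["is_motif"], "sequence"])

    for path in sorted(BASE.glob("pools/R[1-9].tsv")):
        label = path.stem
        pool = RoundPool.read_tsv(path, label, "positive")
        records = top_n(rank_by_enrichment(library, pool), 1000)
        enrichment_frame(records).to_csv(OUT / f"enrichment_{label}.tsv",
                                         sep="\t", index=False)
        top50 = records[:50]
        n_binders = sum(r.sequence in binders for r in top50)
        print(f"{label}: top enrichment {records[0].fold_enrichment:.1f}x, "
              f"{n_binders}/50 of the most enriched sequences are planted binders")


if __name__ == "__main__":
    main()
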