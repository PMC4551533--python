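#!/usr/bin/env python
"""Cluster the most enriched sequences of the final round by identity.

Re-attaches the fixed primers (as in the modeled pipeline), clusters the
top enriched sequences greedily at identity 0.8, and writes the cluster
table plus a FASTA of representatives under results/clusters/.
"""

from pathlib import Path

import pandas as pd

from selexenrich import study
from selexenrich.clustering import greedy_cluster
from selexenrich.readproc import RoundPool

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "clusters"
FINAL = "R3"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    enr = pd.read_csv(BASE / "enrichment" / f"enrichment_{FINAL}.tsv", sep="\t")
    pool = RoundPool.read_tsv(BASE / "pools" / f"{FINAL}.tsv", FINAL, "positive")

    seq_counts = [
        (f"{study.FORWARD_PRIMER}{seq}{study.REVERSE_PRIMER_SITE}", pool.count_of(seq))
        for seq in enr["sequence"]
    ]
    clusters = greedy_cluster(seq_counts, threshold=0.8)

    pd.DataFrame(
        [(c.cluster_id, c.representative, m, ident, c.size)
         for c in clusters for m, ident in c.members],
        columns=["cluster_id", "representative", "member", "identity", "size"],
    ).to_csv(OUT / f"clusters_{FINAL}.tsv", sep="\t", index=False)

    with open(OUT / f"representatives_{FINAL}.fasta", "w") as fh:
        for c in clusters:
            fh.write(f">cluster_{c.cluster_id} size={c.size}\n{c.representative}\n")

    sizes = sorted((c.size for c in clusters), reverse=True)
    print(f"{FINAL}: {len(seq_counts)} sequences -> {len(clusters)} clusters; "
          f"largest sizes {sizes[:5]}")


if __name__ == "__main__":
    main()
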