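#!/usr/bin/env python
"""Build the candidate-aptamer report with all screening flags.

Joins the final-round enrichment ranking with cluster sizes, marks
sequences found in negative pools, abundant-library homologs, and
parasites, and checks the verdicts against the simulation ground truth.
Writes results/candidates.tsv.
"""

from pathlib import Path

import pandas as pd

from selexenrich import study
from selexenrich.candidates import build_candidate_table, candidate_frame
from selexenrich.clustering import Cluster
from selexenrich.enrichment import EnrichmentRecord
from selexenrich.readproc import RoundPool

BASE = Path(__file__).resolve().parent.parent / "results"
FINAL = "R3"


def main() -> None:
    library = RoundPool.read_tsv(BASE / "pools" / "R0.tsv", "R0", "unselected", "free")
    positives = [RoundPool.read_tsv(p, p.stem, "positive")
                 for p in sorted(BASE.glob("pools/R[1-9].tsv"))]
    negatives = [RoundPool.read_tsv(p, p.stem.replace("neg", "-"), "negative")
                 for p in sorted(BASE.glob("pools/*neg.tsv"))]

    enr_df = pd.read_csv(BASE / "enrichment" / f"enrichment_{FINAL}.tsv", sep="\t").head(50)
    records = [EnrichmentRecord(**row) for row in enr_df.to_dict("records")]

    cl_df = pd.read_csv(BASE / "clusters" / f"clusters_{FINAL}.tsv", sep="\t")
    clusters = [
        Cluster(cid, grp["representative"].iloc[0],
                list(zip(grp["member"], grp["identity"])))
        for cid, grp in cl_df.groupby("cluster_id")
    ]

    rows = build_candidate_table(
        records, clusters, negatives, library,
        positive_pools=positives,
        fwd_primer=study.FORWARD_PRIMER, rev_primer=study.REVERSE_PRIMER_SITE,
    )
    df = candidate_frame(rows)
    df.to_csv(BASE / "candidates.tsv", sep="\t", index=False)

    truth = pd.read_csv(BASE / "sim" / "ground_truth.tsv", sep="\t").set_index("sequence")
    df["truth_binder"] = df["sequence"].map(truth["is_motif"]).fillna(False)
    clean = df[~df["in_negative_pool"] & ~df["is_parasite"] & (df["n_library_homologs"] == 0)]
    print(f"{len(df)} candidates: {int(df['truth_binder'].sum())} planted binders, "
          f"{int(df['is_parasite'].sum())} flagged parasitic, "
          f"{len(clean)} clean")
    print(f"clean candidates that are true binders: "
          f"{int(clean['truth_binder'].sum())}/{len(clean)}")


if __name__ == "__main__":
    main()
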