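#!/usr/bin/env python
"""Simulate a CE-SELEX selection and write the raw per-round FASTQ files.

Three positive rounds at decreasing target concentration with negative
(counter-selection) pools branching at rounds 1 and 2, sequenced at
20,000 reads per round so the whole analysis chain runs in seconds.
Writes the FASTQs, the ground-truth labels, and the simulation config
under results/sim/.
"""

from pathlib import Path

import pandas as pd
import yaml

from selexenrich import study
from selexenrich.simdata import SimConfig, simulate_selex, write_round_fastq

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=2026, n_rounds=3, depth_per_round=20_000,
                       negative_rounds=(1, 2))
    run = simulate_selex(config)

    for pool in run.all_pools():
        path = OUT / f"{pool.round_label.replace('-', 'neg')}.fastq"
        write_round_fastq(pool, study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE,
                          study.ILLUMINA_ADAPTOR, path)
        print(f"wrote {path.name}: {pool.total_reads} reads, {pool.n_unique} unique")

    truth = pd.DataFrame(
        [(s, kd, m, p) for s, (kd, m, p) in run.truth.entries.items()],
        columns=["sequence", "kd_nM", "is_motif", "is_parasite"],
    )
    truth.to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    with open(OUT / "sim_config.yaml", "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in config.__dict__.items()}, fh)

    n_binders = len(run.truth.motif_sequences)
    print(f"planted {n_binders} motif-bearing binder sequences, "
          f"{config.parasite_count} parasites, adaptor at {config.adaptor_fraction:.0%}")


if __name__ == "__main__":
    main()
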