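from __future__ import annotations

import numpy as np
import pytest

from selexenrich import study
from selexenrich.enrichment import fold_enrichment, rank_by_enrichment
from selexenrich.readproc import duplication_percent, process_fastq
from selexenrich.simdata import (
    SimConfig,
    make_library,
    simulate_binding_assay,
    simulate_round,
    simulate_selex,
    write_round_fastq,
)


def base_frequencies(pool):
    counts = np.zeros(4)
    total = 0
    for rec in pool.records:
        for i, b in enumerate("ACGT"):
            counts[i] += rec.sequence.count(b) * rec.count
        total += len(rec.sequence) * rec.count
    return counts / total


class TestMakeLibrary:
    def test_uniform_base_probs_recovered(self):
        config = SimConfig(seed=0, depth_per_round=10_000,
                           base_probs=(0.25, 0.25, 0.25, 0.25),
                           parasite_count=0, adaptor_fraction=0.0)
        pool, _ = make_library(config)
        freqs = base_frequencies(pool)
        sigma = np.sqrt(0.25 * 0.75 / (10_000 * 25))
        assert np.all(np.abs(freqs - 0.25) < 3 * sigma)

    def test_thymine_bias_reproduced(self):
        config = SimConfig(seed=1, depth_per_round=10_000,
                           base_probs=(0.2, 0.2, 0.2, 0.4),
                           parasite_count=0, adaptor_fraction=0.0)
        pool, _ = make_library(config)
        assert base_frequencies(pool)[3] == pytest.approx(0.4, abs=0.01)

    def test_adaptor_contaminant_tops_the_library(self):
        config = SimConfig(seed=2, depth_per_round=10_000, adaptor_fraction=0.05)
        pool, truth = make_library(config)
        assert pool.records[0].sequence == config.adaptor_sequence
        assert pool.records[0].count == 500
        assert not truth.is_parasite(config.adaptor_sequence)

    def test_depth_is_exact_and_truth_covers_pool(self):
        config = SimConfig(seed=3, depth_per_round=5_000)
        pool, truth = make_library(config)
        assert pool.total_reads == 5_000
        assert all(r.sequence in truth.entries for r in pool.records)

    def test_parasites_spiked_at_configured_fraction(self):
        config = SimConfig(seed=4, depth_per_round=20_000)
        pool, truth = make_library(config)
        for seq in truth.parasite_sequences:
            assert pool.count_of(seq) >= int(config.parasite_init_frac * 20_000)
        assert len(truth.parasite_sequences) == config.parasite_count

    def test_motif_longer_than_region_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(motif="A" * 30)


class TestSimulateRound:
    def small_config(self, **kw):
        defaults = dict(seed=5, n_rounds=3, depth_per_round=20_000, negative_rounds=())
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_depth_per_round_exact(self):
        run = simulate_selex(self.small_config())
        for pool in run.positives:
            assert pool.total_reads == 20_000

    def test_motif_fraction_strictly_increases_under_selection(self):
        # Kd_motif << protein conc << Kd_bg, no artifact species competing
        run = simulate_selex(self.small_config(
            Kd_motif=0.5, parasite_count=0, adaptor_fraction=0.0))
        fracs = []
        for pool in [run.library, *run.positives]:
            f = sum(r.count for r in pool.records if run.truth.entries[r.sequence][1])
            fracs.append(f / pool.total_reads)
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_negative_round_does_not_boost_binders(self):
        config = self.small_config(negative_rounds=(1,))
        run = simulate_selex(config)
        neg = run.negatives["R1-"]
        feeding = run.positives[0]
        binder_neg = sum(r.count for r in neg.records if run.truth.entries[r.sequence][1])
        binder_pos = sum(r.count for r in feeding.records if run.truth.entries[r.sequence][1])
        assert binder_neg / neg.total_reads < binder_pos / feeding.total_reads

    def test_duplication_grows_under_selective_pressure(self):
        run = simulate_selex(self.small_config())
        assert duplication_percent(run.final_round) > duplication_percent(run.library)

    def test_null_selection_preserves_expected_frequencies(self):
        """No affinity differences, no parasites, no contamination: the
        median fold enrichment across surviving sequences stays near 1.
        A short region keeps the sequence space far smaller than the depth
        so the estimate is not distorted by survivorship."""
        config = SimConfig(seed=6, n_rounds=2, depth_per_round=30_000,
                           region_length=6, motif="ACGTAC",
                           Kd_motif=1e5, Kd_bg=1e5, parasite_count=0,
                           adaptor_fraction=0.0, negative_rounds=())
        run = simulate_selex(config)
        recs = rank_by_enrichment(run.library, run.final_round)
        med = np.median([r.fold_enrichment for r in recs])
        assert med == pytest.approx(1.0, abs=0.25)

    def test_bit_reproducible_from_seed(self, tmp_path):
        config = self.small_config(seed=7, depth_per_round=5_000)
        a, b = simulate_selex(config), simulate_selex(config)
        assert a.library.records == b.library.records
        assert all(x.records == y.records for x, y in zip(a.positives, b.positives))
        pa, pb = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_round_fastq(a.final_round, study.FORWARD_PRIMER,
                          study.REVERSE_PRIMER_SITE, "ACGT", pa)
        write_round_fastq(b.final_round, study.FORWARD_PRIMER,
                          study.REVERSE_PRIMER_SITE, "ACGT", pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_empty_pool_rejected(self):
        config = self.small_config()
        _, truth = make_library(config)
        from selexenrich.readproc import RoundPool
        empty = RoundPool("R1", "positive", "bound", [])
        with pytest.raises(ValueError):
            simulate_round(empty, truth, 50.0, False, config, np.random.default_rng(0))


class TestWriteRoundFastq:
    def test_roundtrip_through_readproc(self, tmp_path):
        config = SimConfig(seed=8, depth_per_round=2_000)
        pool, _ = make_library(config)
        path = tmp_path / "r0.fastq"
        write_round_fastq(pool, study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE,
                          study.ILLUMINA_ADAPTOR, path)
        out, report = process_fastq(path, "R0", "unselected",
                                    study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE)
        assert out.records == pool.records
        assert report.reads_accepted == pool.total_reads

    def test_empty_pool_writes_valid_empty_fastq(self, tmp_path):
        from selexenrich.readproc import RoundPool, read_fastq
        path = tmp_path / "empty.fastq"
        write_round_fastq(RoundPool("R0", "unselected", "free", []),
                          study.FORWARD_PRIMER, study.REVERSE_PRIMER_SITE, "", path)
        assert path.exists() and list(read_fastq(path)) == []


class TestSimulateBindingAssay:
    def test_zero_noise_returns_exact_model_values(self):
        from selexenrich.binding import isotherm_signal
        grid = [0.0, 50.0, 100.0, 250.0, 500.0, 750.0]
        data = simulate_binding_assay(280.0, 100.0, 0.1, grid,
                                      noise_sd=0.0, replicates=2, seed=0)
        assert len(data) == 12
        for p in data:
            assert p.signal == pytest.approx(isotherm_signal(p.T, 100.0, 280.0, 0.1))

    def test_reproducible_from_seed(self):
        grid = [0.0, 50.0, 200.0]
        a = simulate_binding_assay(280.0, 100.0, 0.1, grid, seed=42)
        b = simulate_binding_assay(280.0, 100.0, 0.1, grid, seed=42)
        assert a == b

    def test_more_replicates_shrink_kd_standard_error(self):
        from selexenrich.binding import fit_isotherm
        grid = [0.0, 10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 240.0]
        ses = []
        for reps in (2, 8):
            vals = []
            for seed in range(15):
                data = simulate_binding_assay(100.0, 10.0, 1.0, grid,
                                              noise_sd=0.02, replicates=reps, seed=seed)
                vals.append(fit_isotherm(data, A=10.0).se_Kd)
            ses.append(np.mean(vals))
        assert ses[1] < ses[0]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_binding_assay(0.0, 10.0, 1.0, [0, 10, 20, 40])
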