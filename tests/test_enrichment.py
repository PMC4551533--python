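from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selexenrich.enrichment import (
    fold_enrichment,
    frequency_table,
    rank_by_enrichment,
    top_n,
)
from selexenrich.simdata import SimConfig, simulate_selex

from conftest import make_pool


class TestFrequencyTable:
    def test_normalizes_counts(self):
        ft = frequency_table(make_pool({"A": 3, "B": 1}))
        assert ft.freqs == {"A": 0.75, "B": 0.25}

    def test_single_record_has_frequency_one(self):
        assert frequency_table(make_pool({"A": 7})).freqs == {"A": 1.0}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            frequency_table(make_pool({}))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=5, max_size=5),
                           st.integers(min_value=1, max_value=1000),
                           min_size=1, max_size=30))
    def test_frequencies_sum_to_one(self, counts):
        ft = frequency_table(make_pool(counts))
        assert sum(ft.freqs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(f > 0 for f in ft.freqs.values())


class TestFoldEnrichment:
    def test_frequency_ratio(self):
        ref = make_pool({"S": 10, "X": 990}, "R0", "unselected")
        target = make_pool({"S": 40, "X": 1960}, "R1")
        assert fold_enrichment("S", ref, target) == pytest.approx(2.0)

    def test_identical_frequencies_give_one(self):
        ref = make_pool({"S": 5, "X": 95}, "R0", "unselected")
        target = make_pool({"S": 10, "X": 190}, "R1")
        assert fold_enrichment("S", ref, target) == pytest.approx(1.0)

    def test_pseudocount_for_absent_reference_sequence(self):
        ref = make_pool({"X": 1000}, "R0", "unselected")
        target = make_pool({"S": 50, "X": 1950}, "R1")
        # (50/2000) / (1/1000) = 25
        assert fold_enrichment("S", ref, target, pseudocount=1) == pytest.approx(25.0)

    def test_absent_from_target_is_an_error(self):
        ref = make_pool({"S": 1}, "R0", "unselected")
        target = make_pool({"X": 1}, "R1")
        with pytest.raises(ValueError):
            fold_enrichment("S", ref, target)

    def test_zero_pseudocount_with_absent_reference(self):
        ref = make_pool({"X": 1000}, "R0", "unselected")
        target = make_pool({"S": 50, "X": 1950}, "R1")
        with pytest.raises(ZeroDivisionError):
            fold_enrichment("S", ref, target, pseudocount=0)


class TestRankByEnrichment:
    def test_most_enriched_ranks_first(self):
        ref = make_pool({"A": 1, "B": 1, "X": 998}, "R0", "unselected")
        target = make_pool({"A": 26, "B": 22, "X": 952}, "R1")
        recs = rank_by_enrichment(ref, target)
        assert [(r.sequence, r.rank) for r in recs[:2]] == [("A", 1), ("B", 2)]
        assert recs[0].fold_enrichment > recs[1].fold_enrichment

    def test_flat_pools_all_enrichment_one(self):
        ref = make_pool({"A": 2, "B": 2, "C": 2}, "R0", "unselected")
        target = make_pool({"A": 5, "B": 5, "C": 5}, "R1")
        recs = rank_by_enrichment(ref, target)
        assert all(r.fold_enrichment == pytest.approx(1.0) for r in recs)
        # tie-break: equal counts -> lexicographic
        assert [r.sequence for r in recs] == ["A", "B", "C"]

    def test_ties_broken_by_target_count_then_sequence(self):
        ref = make_pool({"A": 1, "B": 2, "X": 97}, "R0", "unselected")
        target = make_pool({"A": 2, "B": 4, "X": 94}, "R1")
        recs = rank_by_enrichment(ref, target)
        assert [r.sequence for r in recs[:2]] == ["B", "A"]

    def test_rank_invariant_to_input_record_order(self):
        rng = np.random.default_rng(3)
        seqs = [f"S{i:02d}" for i in range(15)]
        ref_counts = {s: int(rng.integers(1, 50)) for s in seqs}
        tgt_counts = {s: int(rng.integers(1, 50)) for s in seqs}
        ref = make_pool(ref_counts, "R0", "unselected")
        target = make_pool(tgt_counts, "R1")
        shuffled = make_pool(dict(reversed(list(tgt_counts.items()))), "R1")
        assert rank_by_enrichment(ref, target) == rank_by_enrichment(ref, shuffled)

    def test_agrees_with_bruteforce_on_small_pools(self):
        """Oracle: recompute every enrichment and the full ordering directly
        from the raw count dictionaries."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 21))
            seqs = [f"S{i:02d}" for i in range(n)]
            ref_counts = {s: int(rng.integers(0, 30)) for s in seqs}
            tgt_counts = {s: int(rng.integers(1, 30)) for s in seqs}
            ref_counts["PAD"] = 50  # keep reference non-degenerate
            ref = make_pool({k: v for k, v in ref_counts.items() if v > 0}, "R0", "unselected")
            target = make_pool(tgt_counts, "R1")

            rt, tt = ref.total_reads, target.total_reads
            expected = sorted(
                (
                    (-(tgt_counts[s] / tt) / (max(ref_counts.get(s, 0), 1) / rt),
                     -tgt_counts[s], s)
                    for s in tgt_counts
                ),
            )
            got = rank_by_enrichment(ref, target)
            assert [r.sequence for r in got] == [s for *_f, s in expected]
            for rec in got:
                fe = (tgt_counts[rec.sequence] / tt) / (max(ref_counts.get(rec.sequence, 0), 1) / rt)
                assert rec.fold_enrichment == pytest.approx(fe)

    def test_scale_invariance(self):
        ref_counts = {"A": 1, "B": 3, "X": 96}
        tgt_counts = {"A": 9, "B": 5, "X": 86}
        ref = make_pool(ref_counts, "R0", "unselected")
        target = make_pool(tgt_counts, "R1")
        ref7 = make_pool({s: 7 * c for s, c in ref_counts.items()}, "R0", "unselected")
        target7 = make_pool({s: 7 * c for s, c in tgt_counts.items()}, "R1")
        base, scaled = rank_by_enrichment(ref, target), rank_by_enrichment(ref7, target7)
        for r1, r2 in zip(base, scaled):
            assert (r1.sequence, r1.rank) == (r2.sequence, r2.rank)
            assert r1.fold_enrichment == pytest.approx(r2.fold_enrichment)

    def test_strictly_larger_frequency_rise_ranks_above(self):
        ref = make_pool({"A": 10, "B": 10, "X": 80}, "R0", "unselected")
        target = make_pool({"A": 30, "B": 20, "X": 50}, "R1")
        recs = {r.sequence: r.rank for r in rank_by_enrichment(ref, target)}
        assert recs["A"] < recs["B"]


class TestTopN:
    def test_truncates_to_n(self):
        ref = make_pool({f"S{i:04d}": 1 for i in range(1500)}, "R0", "unselected")
        target = make_pool({f"S{i:04d}": i + 1 for i in range(1500)}, "R1")
        recs = top_n(rank_by_enrichment(ref, target), 1000)
        assert len(recs) == 1000
        assert [r.rank for r in recs] == list(range(1, 1001))

    def test_short_list_returned_whole(self):
        ref = make_pool({f"S{i}": 1 for i in range(10)}, "R0", "unselected")
        recs = rank_by_enrichment(ref, make_pool({f"S{i}": 2 for i in range(10)}, "R1"))
        assert len(top_n(recs, 1000)) == 10

    def test_n_one_returns_single_most_enriched(self):
        ref = make_pool({"A": 1, "B": 5, "X": 94}, "R0", "unselected")
        target = make_pool({"A": 10, "B": 10, "X": 80}, "R1")
        assert [r.sequence for r in top_n(rank_by_enrichment(ref, target), 1)] == ["A"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n([], 0)


def test_planted_binders_outenrich_background():
    """On a simulated selection the median fold enrichment (library to final
    round) of motif-bearing sequences exceeds the background median."""
    config = SimConfig(seed=5, n_rounds=2, depth_per_round=20_000, negative_rounds=())
    run = simulate_selex(config)
    lib, final, truth = run.library, run.final_round, run.truth
    recs = rank_by_enrichment(lib, final)
    motif_fe = [r.fold_enrichment for r in recs if truth.entries[r.sequence][1]]
    bg_fe = [r.fold_enrichment for r in recs
             if not truth.entries[r.sequence][1] and not truth.entries[r.sequence][2]]
    assert motif_fe and bg_fe
    assert np.median(motif_fe) > np.median(bg_fe)
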