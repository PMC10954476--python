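"""Fragment deduplication, per-dyad classification and level calling."""

import random

import numpy as np
import pandas as pd
import pytest

from hemidyad import (
    CallerConfig,
    DigestionParams,
    FragmentRecord,
    LibraryParams,
    Methylome,
    call_cytosine_levels,
    classify_fragment_vs_dyad,
    count_dyad_statuses,
    dedup_fragments,
    dyad_levels,
    predominant_status,
    scan_dyads,
    simulate_library,
)
from hemidyad.caller import DyadCallCounts
from hemidyad.genome import Genome
from hemidyad.synthetic import make_construct_methylome

from conftest import UNIT_DIGESTION


def frag(start, end, umi="AAAA", chrom="construct"):
    return FragmentRecord(chrom, start, end, umi=umi)


class TestDedup:
    def test_same_position_same_umi_collapses(self):
        assert len(dedup_fragments([frag(0, 50), frag(0, 50)])) == 1

    def test_same_position_different_umi_kept(self):
        assert len(dedup_fragments([frag(0, 50, "AAAA"), frag(0, 50, "CCCC")])) == 2

    def test_empty_input(self):
        assert dedup_fragments([]) == []

    def test_retention_is_order_independent(self):
        frags = [frag(0, 50), frag(10, 60), frag(0, 50, "CCCC"), frag(0, 50)]
        assert dedup_fragments(frags) == dedup_fragments(list(reversed(frags)))


class TestClassify:
    """The construct dyad (Watson C at 72) has cut offsets L=57, R=89."""

    @pytest.mark.parametrize(
        "interval,status",
        [
            ((57, 89), "me"),  # the doubly-cut 32-mer
            ((0, 89), "hemiW"),  # only the Watson-side cut fired
            ((57, 146), "hemiC"),
            ((0, 146), "unme"),  # spans both cut sites, no matching edge
            ((60, 89), "strand_only_W"),  # partner cut site outside the fragment
            ((57, 80), "strand_only_C"),
            ((10, 50), "no_call"),
            ((58, 88), "no_call"),  # shorter than the dyad interval, no edge
        ],
    )
    def test_construct_fragments(self, construct, interval, status):
        _, dyad = construct
        assert classify_fragment_vs_dyad(frag(*interval), dyad) == status

    def test_non_resolvable_dyad_rejected(self):
        (dyad,) = scan_dyads(Genome({"c": "AACGTG"}), "CpG")
        with pytest.raises(ValueError, match="not resolvable"):
            classify_fragment_vs_dyad(frag(0, 30, chrom="c"), dyad)


class TestCountDyadStatuses:
    def test_round_trip_single_status_dyads(self, construct):
        """An always-hemiW construct produces only hemiW calls."""
        genome, dyad = construct
        meth = make_construct_methylome(genome, dyad, True, False)
        frags = simulate_library(
            genome, meth, UNIT_DIGESTION, LibraryParams(n_molecules=20, seed=0)
        )
        calls = count_dyad_statuses(frags, [dyad])
        row = calls.iloc[0]
        assert row["hemiW"] > 0
        assert row[["unme", "hemiC", "me"]].sum() == 0
        assert not row["excluded"]

    def test_coverage_threshold_follows_more_than_four_reads(self, construct):
        _, dyad = construct
        frags = [frag(57, 89, umi=f"U{i}") for i in range(4)]
        calls = count_dyad_statuses(frags, [dyad])
        assert calls.iloc[0]["coverage"] == 4 and bool(calls.iloc[0]["excluded"])
        frags.append(frag(57, 89, umi="U5"))
        calls = count_dyad_statuses(frags, [dyad])
        assert not calls.iloc[0]["excluded"]

    def test_no_fragments_means_excluded(self, construct):
        _, dyad = construct
        calls = count_dyad_statuses([], [dyad])
        assert calls.iloc[0]["coverage"] == 0 and bool(calls.iloc[0]["excluded"])

    def test_input_order_invariance(self, small_genome, designed_run):
        _, _, fragments = designed_run
        dyads = [d for d in scan_dyads(small_genome, "CpG") if d.resolvable]
        shuffled = fragments.copy()
        random.Random(5).shuffle(shuffled)
        a = count_dyad_statuses(fragments, dyads)
        b = count_dyad_statuses(shuffled, dyads)
        pd.testing.assert_frame_equal(a, b)

    def test_strand_only_evidence_not_in_coverage(self, construct):
        _, dyad = construct
        frags = [frag(60, 89, umi=f"U{i}") for i in range(6)]
        calls = count_dyad_statuses(frags, [dyad])
        row = calls.iloc[0]
        assert row["strand_only_W"] == 6 and row["coverage"] == 0

    def test_round_trip_recovers_designed_statuses(self, small_genome, designed_run):
        """Under idealized digestion the caller recovers every designed
        dyad status at full coverage."""
        methylome, truth, fragments = designed_run
        dyads = [d for d in scan_dyads(small_genome, "CpG") if d.resolvable]
        calls = count_dyad_statuses(fragments, dyads)
        merged = truth.merge(calls, on=["chrom", "watson_c"])
        assert len(merged) == len(truth)
        passing = merged[merged["coverage"] >= 5]
        # long unmethylated stretches can exceed the size-selection window
        # and lose coverage (the method under-represents them), but the
        # vast majority of designed dyads must pass
        assert len(passing) >= 0.9 * len(merged)
        for row in passing.itertuples():
            called = predominant_status(
                {s: getattr(row, s) for s in ("unme", "hemiW", "hemiC", "me")},
                min_count=1,
            )
            assert called == row.status


class TestCytosineLevels:
    def test_levels_from_constructed_edges(self):
        sites = [("c", 10, "+")]  # breakpoint at 27
        frags = (
            [FragmentRecord("c", 0, 27, umi=f"M{i}") for i in range(8)]
            + [FragmentRecord("c", 0, 100, umi=f"U{i}") for i in range(2)]
        )
        levels = call_cytosine_levels(frags, sites)
        row = levels.iloc[0]
        assert (row["meth"], row["unmeth"]) == (8, 2)
        assert row["level"] == pytest.approx(0.8)

    def test_uncovered_site_is_nan_and_excluded(self):
        levels = call_cytosine_levels([], [("c", 10, "+")])
        assert np.isnan(levels.iloc[0]["level"]) and bool(levels.iloc[0]["excluded"])

    def test_partial_efficiency_recovers_cut_rate(self):
        """An always-methylated CGNA-class site read at ~80% cutting
        efficiency shows a level of ~0.80 (the under-estimation the
        efficiency correction exists for)."""
        genome = Genome({"c": "T" * 60 + "TACGAA" + "T" * 80})
        # Watson site of the dyad at 62, CGNA class
        meth = Methylome.from_records([("c", 62, "+", 1.0, "CpG", "A")])
        frags = simulate_library(
            genome,
            meth,
            DigestionParams(efficiency_by_r={"G": 0.97, "A": 0.80}),
            LibraryParams(n_molecules=10_000, seed=9),
        )
        levels = call_cytosine_levels(frags, [("c", 62, "+")], CallerConfig(dedup=False))
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert levels.iloc[0]["level"] == pytest.approx(0.80, abs=3 * se)


class TestDyadLevels:
    def test_pure_hemi_watson(self):
        fractions = dyad_levels({"unme": 0, "hemiW": 5, "hemiC": 0, "me": 0})
        assert fractions["hemiW"] == 1.0

    def test_fractions_sum_to_one(self):
        fractions = dyad_levels({"unme": 2, "hemiW": 1, "hemiC": 1, "me": 4})
        assert fractions["me"] == pytest.approx(0.5)
        assert sum(fractions[s] for s in ("unme", "hemiW", "hemiC", "me")) == 1.0

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError, match="zero"):
            dyad_levels({"unme": 0, "hemiW": 0, "hemiC": 0, "me": 0})

    def test_accepts_dataclass_counts(self, construct):
        _, dyad = construct
        counts = DyadCallCounts(dyad=dyad, me=3, hemiW=1)
        assert dyad_levels(counts)["me"] == pytest.approx(0.75)
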