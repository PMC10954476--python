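"""The four expected-count equations, their inversion, and the empirical
multinomial oracle from the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemidyad import (
    CallerConfig,
    DigestionParams,
    DyadCountVector,
    EfficiencyParams,
    LibraryParams,
    MethylomeDesign,
    assign_efficiencies,
    count_dyad_statuses,
    forward_expected,
    invert_observed,
    make_genome,
    make_methylome,
    plant_construct,
    scan_dyads,
    simulate_library,
)
from hemidyad.normalization import normalize_table

PARAMS = EfficiencyParams(e_watson=0.97, e_crick=0.80, e_pu=1.0)

counts_strategy = st.builds(
    DyadCountVector,
    m=st.floats(0, 1e4),
    w=st.floats(0, 1e4),
    c=st.floats(0, 1e4),
    u=st.floats(0, 1e4),
)
params_strategy = st.builds(
    EfficiencyParams,
    e_watson=st.floats(0.05, 1),
    e_crick=st.floats(0.05, 1),
    e_pu=st.floats(0.05, 1),
)


class TestForward:
    def test_all_me_leaks_into_hemi_and_unme(self):
        expected = forward_expected(DyadCountVector(100, 0, 0, 0), PARAMS)
        assert expected.as_tuple() == pytest.approx((77.6, 19.4, 2.4, 0.6))

    def test_unit_efficiencies_are_identity(self):
        real = DyadCountVector(7, 3, 2, 5)
        out = forward_expected(real, EfficiencyParams(1, 1, 1))
        assert out.as_tuple() == real.as_tuple()

    def test_no_fully_methylated_means_no_leakage(self):
        real = DyadCountVector(0, 10, 5, 20)
        out = forward_expected(real, PARAMS)
        assert out.as_tuple() == real.as_tuple()

    def test_total_count_conserved_when_e_pu_is_one(self):
        real = DyadCountVector(40, 25, 10, 25)
        out = forward_expected(real, PARAMS)
        assert out.total == pytest.approx(real.total)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            forward_expected(DyadCountVector(-1, 0, 0, 0), PARAMS)


class TestInvert:
    def test_recovers_all_me(self):
        est, clamped = invert_observed(DyadCountVector(77.6, 19.4, 2.4, 0.6), PARAMS)
        assert est.as_tuple() == pytest.approx((100, 0, 0, 0), abs=1e-9)
        assert not clamped

    def test_purification_loss_triggers_clamping(self):
        params = EfficiencyParams(0.97, 0.80, e_pu=0.5)
        observed = DyadCountVector(38.8, 9.7, 1.2, 0.3)
        est, clamped = invert_observed(observed, params)
        assert est.m == pytest.approx(100)
        assert clamped and est.w == 0.0 and est.c == 0.0 and est.u == 0.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            invert_observed(DyadCountVector(1, 1, 1, 1), EfficiencyParams(0, 1, 1))

    @settings(max_examples=100, derandomize=True)
    @given(counts_strategy, params_strategy)
    def test_round_trip_identity(self, real, params):
        observed = forward_expected(real, params)
        est, _ = invert_observed(observed, params, clamp=False)
        assert est.as_tuple() == pytest.approx(real.as_tuple(), abs=1e-6, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(counts_strategy, params_strategy)
    def test_extended_round_trip_identity(self, real, params):
        observed = forward_expected(real, params, extended=True)
        est, _ = invert_observed(observed, params, extended=True, clamp=False)
        assert est.as_tuple() == pytest.approx(real.as_tuple(), abs=1e-6, rel=1e-9)


class TestAssignEfficiencies:
    def test_r_base_lookup(self):
        genome, dyad = plant_construct()
        # both strands of the construct dyad are CGNA class
        params = assign_efficiencies(dyad)
        assert (params.e_watson, params.e_crick) == (0.80, 0.80)

    def test_mixed_classes(self):
        from hemidyad.genome import DyadSite

        dyad = DyadSite("c", 10, 11, "CpG", True, "G", "A")
        params = assign_efficiencies(dyad)
        assert (params.e_watson, params.e_crick) == (0.97, 0.80)

    def test_unit_table(self):
        from hemidyad.genome import DyadSite

        dyad = DyadSite("c", 10, 11, "CpG", True, "G", "G")
        params = assign_efficiencies(dyad, {"G": 1.0, "A": 1.0})
        assert (params.e_watson, params.e_crick) == (1.0, 1.0)

    def test_unresolvable_dyad_rejected(self):
        from hemidyad.genome import DyadSite

        dyad = DyadSite("c", 10, 11, "CpG", False, None, None)
        with pytest.raises(ValueError):
            assign_efficiencies(dyad)


class TestSimulatorOracle:
    def test_observed_fractions_match_forward_equations(self):
        """Multinomial status counts from the full simulate-and-call path
        converge to the forward equations' predictions: the equations and
        the simulator describe the same digestion process."""
        genome = make_genome(1500, seed=30)
        methylome, truth = make_methylome(
            genome, MethylomeDesign(status_probs={"me": 1.0}), seed=31
        )
        n = 10_000
        fragments = simulate_library(
            genome,
            methylome,
            DigestionParams(),
            LibraryParams(n_molecules=n, seed=32),
        )
        dyads = [d for d in scan_dyads(genome, "CpG") if d.resolvable]
        calls = count_dyad_statuses(fragments, dyads, CallerConfig(dedup=False))
        merged = truth.merge(calls, on=["chrom", "watson_c"])
        assert len(merged) == len(truth) > 0
        assert (merged["coverage"] == n).all()
        eff = {"G": 0.97, "A": 0.80}
        # pool dyads of the same (r_watson, r_crick) efficiency class so each
        # comparison runs at its pooled sample size
        for (rw, rc), group in merged.groupby(["r_watson_x", "r_crick_x"]):
            ew, ec = eff[rw], eff[rc]
            pooled_n = n * len(group)
            probs = {
                "me": ew * ec,
                "hemiW": ew * (1 - ec),
                "hemiC": (1 - ew) * ec,
                "unme": (1 - ew) * (1 - ec),
            }
            for status, p in probs.items():
                se = np.sqrt(p * (1 - p) / pooled_n)
                observed = group[status].sum() / pooled_n
                assert observed == pytest.approx(p, abs=3 * se + 1e-9)

    def test_normalize_table_restores_me(self):
        genome = make_genome(1500, seed=30)
        methylome, truth = make_methylome(
            genome, MethylomeDesign(status_probs={"me": 1.0}), seed=31
        )
        fragments = simulate_library(
            genome, methylome, DigestionParams(), LibraryParams(n_molecules=3000, seed=33)
        )
        dyads = [d for d in scan_dyads(genome, "CpG") if d.resolvable]
        calls = count_dyad_statuses(fragments, dyads, CallerConfig(dedup=False))
        calls = truth.merge(calls, on=["chrom", "watson_c"], suffixes=("_t", ""))
        corrected = normalize_table(calls)
        totals = corrected[["me_corr", "hemiW_corr", "hemiC_corr", "unme_corr"]].sum()
        props = totals / totals.sum()
        assert props["me_corr"] == pytest.approx(1.0, abs=0.02)
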