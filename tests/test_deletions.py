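"""Tests for pair-gap computation, tail selection and deletion calling."""

import numpy as np
import pytest

from quasipop.deletions import (
    PairGap,
    call_deletions,
    compute_pair_gaps,
    deleted_fraction,
    deletion_coverage_profile,
    gap_histogram,
    hr_anchoring,
    select_tail,
)
from quasipop.errors import ConfigurationError
from quasipop.simulate import (
    Deletion,
    DeletionSpec,
    HaplotypeSet,
    PopulationSpec,
    build_population,
    simulate_reads,
)

from conftest import SEED, clean_linear_spec, clean_read_spec, make_alignment, make_header


def _pair(name, left_start, left_end, right_start, right_end=None, expected=-42):
    right_end = right_end if right_end is not None else right_start + 151
    inner = right_start - left_end
    return PairGap(name, left_start, left_end, right_start, right_end,
                   inner, inner - expected)


class TestComputePairGaps:
    def test_normal_pair_gap_arithmetic(self):
        header = make_header(30_000)
        alns = [
            make_alignment(header, "p0", 100, "A" * 151),
            make_alignment(header, "p0", 209, "A" * 151, reverse=True, read2=True),
        ]
        gaps, _ = compute_pair_gaps(alns)
        (g,) = gaps
        assert g.inner_gap == -42 and g.implied_deletion == 0

    def test_distant_pair_implies_deletion(self):
        header = make_header(30_000)
        alns = [
            make_alignment(header, "p0", 100, "A" * 151),
            make_alignment(header, "p0", 5_209, "A" * 151, reverse=True, read2=True),
        ]
        gaps, _ = compute_pair_gaps(alns)
        (g,) = gaps
        assert g.inner_gap == 4_958 and g.implied_deletion == 5_000

    def test_unpaired_and_wrapped_excluded(self):
        header = make_header(30_000)
        lone = make_alignment(header, "p1", 100, "A" * 151)
        wrapped = make_alignment(header, "p2", 29_900, "A" * 151)
        wrapped.set_tag("XW", 1)
        wrapped2 = make_alignment(header, "p2", 10, "A" * 151, reverse=True, read2=True)
        wrapped2.set_tag("XW", 1)
        gaps, excl = compute_pair_gaps([lone, wrapped, wrapped2])
        assert gaps == []
        assert excl.unpaired == 1 and excl.wrapped == 1


class TestSelectTail:
    def _gaps(self, inner_gaps):
        return [
            _pair(f"p{i}", 100, 251, 251 + g) for i, g in enumerate(inner_gaps)
        ]

    def test_exact_fraction_and_ordering(self):
        rng = np.random.default_rng(SEED)
        gaps = self._gaps(rng.integers(-60, 500, size=100))
        sel = select_tail(gaps, 0.05)
        assert len(sel.selected) == 5
        floor = min(g.inner_gap for g in sel.selected)
        unselected = [g for g in gaps if g.pair_id not in {s.pair_id for s in sel.selected}]
        assert all(g.inner_gap <= floor for g in unselected)

    def test_ties_broken_stably(self):
        gaps = self._gaps([7] * 40)
        sel = select_tail(gaps, 0.1)
        assert [g.pair_id for g in sel.selected] == [f"p{i}" for i in range(4)]

    def test_min_gap_exclusion_drops_short_gaps(self):
        gaps = self._gaps([2_000, 1_500, 700, 600, 100] + [-42] * 95)
        sel = select_tail(gaps, 0.05, min_gap_exclusion=669)
        assert [g.inner_gap for g in sel.selected] == [2_000, 1_500, 700]

    def test_strict_tail_is_subset_of_loose_tail(self):
        rng = np.random.default_rng(SEED)
        gaps = self._gaps(rng.normal(-42, 20, size=400).astype(int))
        loose = select_tail(gaps, 0.05)
        strict = select_tail(gaps, 0.0281, min_gap_exclusion=0)
        loose_ids = {g.pair_id for g in loose.selected}
        assert {g.pair_id for g in strict.selected} <= loose_ids

    def test_null_library_tail_stays_near_zero(self, tmp_path):
        haps = build_population(clean_linear_spec(genome_length=5_000))
        reads = simulate_reads(haps, clean_read_spec(coverage=50))
        sam = tmp_path / "null.sam"
        reads.write_sam(sam)
        gaps, _ = compute_pair_gaps(sam)
        sel = select_tail(gaps, 0.05)
        assert all(abs(g.implied_deletion) <= 4 * 20 for g in sel.selected)

    def test_bad_fraction_raises(self):
        with pytest.raises(ConfigurationError):
            select_tail(self._gaps([1, 2, 3]), 1.5)


class TestCoverageProfile:
    def test_single_pair_footprints(self):
        sel = select_tail([_pair("p0", 100, 251, 5_209, 5_360)], 0.5)
        cov, _ = deletion_coverage_profile(sel, 6_000)
        assert (cov[100:251] == 1).all()
        assert (cov[5_209:5_360] == 1).all()
        assert cov.sum() == 302

    def test_hr_anchored_peaks_colocate_with_hrs(self, small_sim):
        gaps, _ = compute_pair_gaps(small_sim["sam"])
        sel = select_tail(gaps, 0.05, min_gap_exclusion=669)
        cov, peaks = deletion_coverage_profile(sel, len(small_sim["haps"].consensus))
        assert peaks, "expected deletion hotspots"
        hr_ivs = small_sim["haps"].hr_intervals
        slop = 350  # mates sit within a read+insert of the anchoring hr
        for ps, pe in peaks:
            near_hr = any(ps < e + slop and pe > s - slop for s, e in hr_ivs)
            assert near_hr, f"peak ({ps},{pe}) far from every hr"


class TestCallDeletions:
    def test_bracketing_pairs_merge_to_one_call(self):
        rng = np.random.default_rng(SEED)
        gaps = []
        for i in range(20):
            jitter = int(rng.integers(0, 30))
            left_end = 10_000 - jitter
            right_start = 15_000 + int(rng.integers(0, 30))
            gaps.append(_pair(f"p{i}", left_end - 151, left_end, right_start))
        sel = select_tail(gaps, 0.999)
        calls = call_deletions(sel, min_support=5)
        (call,) = calls
        assert call.support == 20
        assert abs(call.start - 10_000) < 260 and abs(call.end - 15_000) < 260
        assert call.boundary_uncertainty <= 30

    def test_two_distant_deletions_not_merged(self):
        gaps = [
            _pair(f"a{i}", 1_000 - 151, 1_000, 4_000) for i in range(6)
        ] + [
            _pair(f"b{i}", 31_000 - 151, 31_000, 34_000) for i in range(6)
        ]
        sel = select_tail(gaps, 0.999)
        calls = call_deletions(sel, min_support=5)
        assert len(calls) == 2

    def test_singleton_below_support_dropped(self):
        gaps = [_pair("p0", 100, 251, 5_209)]
        sel = select_tail(gaps, 0.999)
        assert call_deletions(sel, min_support=5) == []

    def test_no_deletion_simulations_yield_zero_calls(self, tmp_path):
        """Across 20 seeds, deletion-free libraries produce no calls in the
        min-gap-exclusion mode at min_support >= 5."""
        for seed in range(20):
            haps = build_population(clean_linear_spec(genome_length=5_000, seed=seed))
            reads = simulate_reads(haps, clean_read_spec(coverage=60, seed=seed + 100))
            sam = tmp_path / f"null{seed}.sam"
            reads.write_sam(sam)
            gaps, _ = compute_pair_gaps(sam)
            sel = select_tail(gaps, 0.05, min_gap_exclusion=669)
            assert call_deletions(sel, min_support=5) == []


class TestHrAnchoring:
    HRS = [(1_000, 1_400, "hr1"), (5_000, 5_600, "hr2")]

    def test_both_endpoints_anchored(self):
        sel = select_tail([_pair(f"p{i}", 1_239, 1_390, 5_010) for i in range(6)], 0.999)
        calls = hr_anchoring(call_deletions(sel, 5), self.HRS, anchor_slop=50)
        (call,) = calls
        assert call.left_anchor_hr == "hr1" and call.right_anchor_hr == "hr2"

    def test_hr_free_region_unanchored(self):
        sel = select_tail([_pair(f"p{i}", 2_849, 3_000, 4_000) for i in range(6)], 0.999)
        calls = hr_anchoring(call_deletions(sel, 5), self.HRS, anchor_slop=50)
        (call,) = calls
        assert call.left_anchor_hr is None and call.right_anchor_hr is None

    def test_simulated_hr_pairs_population_doubly_anchored(self, small_sim):
        gaps, _ = compute_pair_gaps(small_sim["sam"])
        sel = select_tail(gaps, 0.05, min_gap_exclusion=669)
        calls = call_deletions(sel, min_support=5)
        assert calls
        hrs = [(s, e, f"hr{i + 1}") for i, (s, e) in enumerate(small_sim["haps"].hr_intervals)]
        calls = hr_anchoring(calls, hrs, anchor_slop=260)
        anchored = [c for c in calls if c.left_anchor_hr and c.right_anchor_hr]
        assert len(anchored) / len(calls) >= 0.9

    def test_overlapping_hrs_rejected(self):
        with pytest.raises(ConfigurationError):
            hr_anchoring([], [(100, 300, "a"), (200, 400, "b")])


class TestDeletedFraction:
    def test_null_fraction_near_zero(self, tmp_path):
        haps = build_population(clean_linear_spec(genome_length=5_000))
        reads = simulate_reads(haps, clean_read_spec(coverage=100))
        sam = tmp_path / "null.sam"
        reads.write_sam(sam)
        gaps, _ = compute_pair_gaps(sam)
        frac, _ci = deleted_fraction(gaps, min_deletion=4 * 20)
        assert frac <= 0.005

    def test_full_carriage_fraction_near_one(self, tmp_path):
        consensus = build_population(clean_linear_spec(genome_length=20_000)).consensus
        haps = HaplotypeSet(consensus, [], [Deletion(10_000, 14_000, 0.999)], [],
                            circular=False)
        reads = simulate_reads(haps, clean_read_spec(coverage=300))
        sam = tmp_path / "full.sam"
        reads.write_sam(sam)
        gaps, _ = compute_pair_gaps(sam)
        window = [g for g in gaps if 10_000 - 170 <= g.left_start <= 10_000 - 90]
        frac, _ci = deleted_fraction(window, min_deletion=2_000)
        assert frac >= 0.9

    def test_empty_gaps_raise(self):
        with pytest.raises(ConfigurationError):
            deleted_fraction([], 100)


def test_gap_histogram_counts_everything():
    gaps = [_pair(f"p{i}", 100, 251, 251 + g) for i, g in enumerate([-42, -42, 0, 500])]
    hist = gap_histogram(gaps, bin_width=10)
    assert hist["count"].sum() == 4
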