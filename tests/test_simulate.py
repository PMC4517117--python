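"""Tests for the population and read simulator."""

import numpy as np
import pysam
import pytest

from quasipop.deletions import compute_pair_gaps
from quasipop.errors import CapacityError, ConfigurationError
from quasipop.simulate import (
    Deletion,
    DeletionSpec,
    HaplotypeSet,
    PopulationSpec,
    ReadSimSpec,
    Variant,
    build_population,
    simulate_reads,
)

from conftest import SEED, clean_linear_spec, clean_read_spec


class TestBuildPopulation:
    def test_empty_spec_yields_empty_truth(self):
        spec = PopulationSpec(
            snp_classes=[], deletion_spec=DeletionSpec(genome_fraction=0.0), seed=SEED
        )
        haps = build_population(spec)
        assert haps.variants == [] and haps.deletions == []
        assert len(haps.consensus) == spec.genome_length
        assert set(haps.consensus) <= set("ACGT")

    def test_class_counts_and_mean_frequencies(self, small_population):
        haps = small_population
        assert len(haps.variants) == 200
        targets = {1: (0.0027, 0.0015), 2: (0.093, 0.02), 3: (0.19, 0.03), 4: (0.35, 0.04)}
        for cls, (mean, sd) in targets.items():
            freqs = [v.frequency for v in haps.variants if v.class_label == cls]
            assert len(freqs) == 50
            # class-wise realised mean within 2 sd-of-the-mean of the target
            assert abs(np.mean(freqs) - mean) < 2 * sd / np.sqrt(len(freqs)) + 0.1 * sd

    def test_hr_anchored_deletions_and_carrier_fraction(self):
        spec = PopulationSpec(seed=SEED + 7)
        haps = build_population(spec)
        assert haps.deletions
        hr_ivs = haps.hr_intervals
        for d in haps.deletions:
            assert any(s <= d.start < e for s, e in hr_ivs), "start not inside an hr"
            assert any(s <= d.end < e for s, e in hr_ivs), "end not inside an hr"
            assert spec.deletion_spec.min_size <= d.size <= spec.deletion_spec.max_size
        total = sum(d.carrier_fraction for d in haps.deletions)
        assert abs(total - 0.25) < 0.01

    def test_hr_pairs_mode_requires_two_hrs(self):
        spec = PopulationSpec(hr_layout=[(2_000, 70, 4)], seed=SEED)
        with pytest.raises(ConfigurationError):
            build_population(spec)

    def test_capacity_error(self):
        spec = PopulationSpec(
            genome_length=1_000,
            hr_layout=[],
            snp_classes=[(2_000, 0.1, 0.01)],
            deletion_spec=DeletionSpec(genome_fraction=0.0),
            seed=SEED,
        )
        with pytest.raises(CapacityError):
            build_population(spec)

    def test_at_content_close_to_target(self):
        haps = build_population(
            PopulationSpec(snp_classes=[], deletion_spec=DeletionSpec(genome_fraction=0.0),
                           hr_layout=[], seed=SEED)
        )
        at = sum(haps.consensus.count(b) for b in "AT") / len(haps.consensus)
        assert abs(at - 0.593) < 0.02


class TestSimulateReads:
    def test_error_free_reads_match_consensus(self, tmp_path):
        haps = build_population(clean_linear_spec())
        reads = simulate_reads(haps, clean_read_spec(coverage=20))
        assert len(reads) == round(5_000 * 20 / 302)
        for pair in reads.pairs[:200]:
            for mate in pair.mates:
                assert mate.seq in haps.consensus
        # inner distance equals insert - 2*read_length for every pair
        for pair in reads.pairs[:200]:
            left, right = pair.mates
            gap = right.pos - (left.pos + 151)
            assert -151 <= gap  # overlapping mates, never colliding coordinates

    def test_modal_mate_overlap_is_42(self, tmp_path):
        haps = build_population(clean_linear_spec(genome_length=10_000))
        # fixed 260 bp insert: the mates must overlap by exactly 2*151-260 = 42
        reads = simulate_reads(haps, clean_read_spec(coverage=50, insert_sd=0.0))
        sam = tmp_path / "a.sam"
        reads.write_sam(sam)
        gaps, _ = compute_pair_gaps(sam)
        inner = np.array([g.inner_gap for g in gaps])
        assert (inner == -42).all()
        # with dispersion the distribution stays centred on -42
        reads = simulate_reads(haps, clean_read_spec(coverage=50))
        sam2 = tmp_path / "b.sam"
        reads.write_sam(sam2)
        gaps2, _ = compute_pair_gaps(sam2)
        assert abs(np.median([g.inner_gap for g in gaps2]) + 42) <= 2

    def test_deletion_carriers_inflate_gap(self, tmp_path):
        consensus = build_population(clean_linear_spec(genome_length=20_000)).consensus
        haps = HaplotypeSet(
            consensus, [], [Deletion(10_000, 15_000, 0.5)], [], circular=False
        )
        reads = simulate_reads(haps, clean_read_spec(coverage=400))
        sam = tmp_path / "d.sam"
        reads.write_sam(sam)
        gaps, _ = compute_pair_gaps(sam)
        window = [g for g in gaps if 10_000 - 170 <= g.left_start <= 10_000 - 90]
        assert len(window) > 100
        inflated = [g.implied_deletion for g in window if g.implied_deletion > 2_500]
        frac = len(inflated) / len(window)
        assert 0.4 < frac < 0.6  # ~half of bracketing pairs come from carriers
        assert abs(np.median(inflated) - 5_000) < 150

    def test_conservation_between_fastq_and_sam(self, tmp_path):
        haps = build_population(clean_linear_spec())
        reads = simulate_reads(haps, clean_read_spec(coverage=10))
        r1, r2, sam = tmp_path / "r1.fq", tmp_path / "r2.fq", tmp_path / "a.sam"
        reads.write_fastq(r1, r2)
        reads.write_sam(sam)
        fq_names = []
        for path in (r1, r2):
            with open(path) as fh:
                fq_names.append({line.strip().split("/")[0][1:] for line in fh if line.startswith("@sim")})
        with pysam.AlignmentFile(str(sam), "r") as fh:
            sam_names = [a.query_name for a in fh]
        expected = {p.name for p in reads.pairs}
        assert fq_names[0] == fq_names[1] == expected
        assert sorted(sam_names) == sorted(list(expected) * 2)

    def test_determinism_byte_identical(self, tmp_path):
        spec = PopulationSpec(seed=SEED + 3)
        rspec = ReadSimSpec(coverage=20, seed=SEED + 4)
        outputs = []
        for tag in ("a", "b"):
            haps = build_population(spec)
            reads = simulate_reads(haps, rspec)
            sam = tmp_path / f"{tag}.sam"
            r1, r2 = tmp_path / f"{tag}1.fq", tmp_path / f"{tag}2.fq"
            reads.write_sam(sam)
            reads.write_fastq(r1, r2)
            outputs.append((sam.read_bytes(), r1.read_bytes(), r2.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_zero_coverage_warns_and_returns_empty(self):
        haps = build_population(clean_linear_spec())
        with pytest.warns(UserWarning):
            reads = simulate_reads(haps, clean_read_spec(coverage=0.001))
        assert len(reads) == 0

    def test_wrapped_pairs_flagged_and_excluded(self, small_sim):
        reads = small_sim["reads"]
        assert reads.n_wrapped > 0
        gaps, excl = compute_pair_gaps(small_sim["sam"])
        assert excl.wrapped == reads.n_wrapped
        assert len(gaps) == len(reads) - reads.n_wrapped

    def test_frequency_recovery_from_ideal_alignments(self, small_sim):
        """Fragment-level alt frequencies track the truth at every locus."""
        import re

        from scipy.stats import binom

        haps = small_sim["haps"]
        reads = small_sim["reads"]
        variants = sorted(haps.variants, key=lambda v: v.locus)
        loci = np.array([v.locus for v in variants])
        alts = [v.alt for v in variants]
        cover = np.zeros(len(loci), dtype=int)
        alt_count = np.zeros(len(loci), dtype=int)
        cig_re = re.compile(r"(?:(\d+)S)?(\d+)M")
        err = small_sim["rspec"].substitution_error
        for pair in reads.pairs:
            seen: dict[int, str] = {}
            for mate in pair.mates:
                pre, m_len = cig_re.match(mate.cigar).groups()
                pre = int(pre or 0)
                m_len = int(m_len)
                lo, hi = np.searchsorted(loci, [mate.pos, mate.pos + m_len])
                for vi in range(lo, hi):
                    if vi not in seen:  # first mate's call wins (fragment-level)
                        seen[vi] = mate.seq[pre + int(loci[vi]) - mate.pos]
            for vi, base in seen.items():
                cover[vi] += 1
                if base == alts[vi]:
                    alt_count[vi] += 1
        inside = tested = 0
        for vi, v in enumerate(variants):
            n = int(cover[vi])
            if n < 10:
                continue
            p_adj = v.frequency * (1 - err) + (1 - v.frequency) * err / 3
            lo, hi = binom.ppf(0.005, n, p_adj), binom.ppf(0.995, n, p_adj)
            tested += 1
            inside += int(lo <= alt_count[vi] <= hi)
        assert tested >= 190
        assert inside / tested >= 0.97
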