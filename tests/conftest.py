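"""Shared fixtures: small simulated populations and SAM record helpers."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from quasipop.pileup import QcPolicy, build_pileup
from quasipop.simulate import (
    DeletionSpec,
    PopulationSpec,
    ReadSimSpec,
    build_population,
    simulate_reads,
)

SEED = 0  # global test seed convention


def make_header(length: int = 20_000, name: str = "consensus") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": name, "LN": length}]}
    )


def make_alignment(
    header: pysam.AlignmentHeader,
    name: str,
    pos: int,
    seq: str,
    qual: int = 34,
    cigar: str | None = None,
    reverse: bool = False,
    read2: bool = False,
    paired: bool = True,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    flag = 0
    if paired:
        flag |= 0x1
        flag |= 0x80 if read2 else 0x40
    if reverse:
        flag |= 0x10
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    return a


@pytest.fixture(scope="session")
def small_population():
    """Default 20 kb population: 4 SNP classes, two hr-anchored deletions (25%)."""
    return build_population(PopulationSpec(seed=SEED))


@pytest.fixture(scope="session")
def small_sim(small_population, tmp_path_factory):
    """300x read simulation over the default population, with SAM on disk."""
    rspec = ReadSimSpec(coverage=300, seed=SEED + 1)
    reads = simulate_reads(small_population, rspec)
    sam = tmp_path_factory.mktemp("sim") / "alignments.sam"
    reads.write_sam(sam)
    return {
        "haps": small_population,
        "rspec": rspec,
        "reads": reads,
        "sam": sam,
    }


@pytest.fixture(scope="session")
def small_pileup(small_sim):
    return build_pileup(
        small_sim["sam"], len(small_sim["haps"].consensus), QcPolicy(), dedup_overlaps=True
    )


def clean_linear_spec(genome_length: int = 5_000, seed: int = SEED) -> PopulationSpec:
    """Linear, deletion-free, variant-free population for null tests."""
    return PopulationSpec(
        genome_length=genome_length,
        hr_layout=[(1_000, 70, 4), (3_000, 70, 6)],
        snp_classes=[],
        deletion_spec=DeletionSpec(genome_fraction=0.0),
        circular=False,
        seed=seed,
    )


def clean_read_spec(coverage: float = 100.0, seed: int = SEED + 1, **kw) -> ReadSimSpec:
    """Error-free, full-quality read model."""
    defaults = dict(
        coverage=coverage, substitution_error=0.0, low_q_run_prob=0.0, seed=seed
    )
    defaults.update(kw)
    return ReadSimSpec(**defaults)
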