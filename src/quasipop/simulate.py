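"""Synthetic genome populations and paired-end read simulation.

This module generates the kind of data the rest of the pipeline assumes: a
circular dsDNA consensus genome carrying homologous repeat regions (hrs),
a population of genomes that differ from the consensus by low- to
high-frequency SNPs (grouped in frequency classes) and by multi-kilobase
deletions anchored in hrs, and Illumina-style 151 bp paired-end reads from
short (~260 bp) inserts whose mates overlap in the middle.

The simulator emits three coupled streams for every run: paired FASTQ reads,
"ideal" single-end alignments on the consensus coordinate system (SAM), and a
machine-readable truth model (`HaplotypeSet`) for parameter-recovery tests.
A mate whose fragment crosses a deletion junction (or the circular origin) is
aligned to the side holding the larger piece of the read, with the remainder
soft-clipped — the behaviour a local single-end aligner shows on such reads.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import CapacityError, ConfigurationError

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# truth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant segregating in the population.

    ``frequency`` is the fraction of genomes carrying ``alt`` at ``locus``
    (0-based, consensus coordinates). ``block`` optionally links variants that
    co-occur on the same genomes (haplotype linkage); ``None`` means the
    variant is assigned to genomes independently of every other variant.
    """

    locus: int
    ref: str
    alt: str
    frequency: float
    class_label: int
    block: int | None = None


@dataclass(frozen=True)
class Deletion:
    """A large deletion ``[start, end)`` carried by a genome subpopulation."""

    start: int
    end: int
    carrier_fraction: float

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeSet:
    """Truth model of a simulated genome population."""

    consensus: str
    variants: list[Variant] = field(default_factory=list)
    deletions: list[Deletion] = field(default_factory=list)
    hr_intervals: list[tuple[int, int]] = field(default_factory=list)
    circular: bool = True

    def validate(self) -> None:
        n = len(self.consensus)
        if set(self.consensus) - set("ACGT"):
            raise ConfigurationError("consensus may contain only A/C/G/T")
        freq_per_locus: dict[int, float] = {}
        for v in self.variants:
            if not 0.0 < v.frequency < 1.0:
                raise ConfigurationError(f"variant frequency {v.frequency} outside (0,1)")
            if not 0 <= v.locus < n:
                raise ConfigurationError(f"variant locus {v.locus} outside genome")
            if self.consensus[v.locus] != v.ref or v.alt == v.ref:
                raise ConfigurationError(f"variant at {v.locus} inconsistent with consensus")
            freq_per_locus[v.locus] = freq_per_locus.get(v.locus, 0.0) + v.frequency
        if any(f >= 1.0 for f in freq_per_locus.values()):
            raise ConfigurationError("total alternate frequency at a locus must stay < 1")
        for d in self.deletions:
            if not (0 <= d.start < d.end <= n):
                raise ConfigurationError(f"deletion {d.start}-{d.end} outside genome")
        if sum(d.carrier_fraction for d in self.deletions) >= 1.0:
            raise ConfigurationError("deletion carrier fractions must sum to < 1")

    # -- writers ------------------------------------------------------------

    def write_consensus(self, path: str | Path, name: str = "consensus") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.consensus), 80):
                fh.write(self.consensus[i : i + 80] + "\n")

    def write_truth(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "variants.tsv", "w") as fh:
            fh.write("locus\tref\talt\tfrequency\tclass\tblock\n")
            for v in self.variants:
                blk = "" if v.block is None else str(v.block)
                fh.write(f"{v.locus}\t{v.ref}\t{v.alt}\t{v.frequency:.6g}\t{v.class_label}\t{blk}\n")
        with open(outdir / "deletions.bed", "w") as fh:
            for i, d in enumerate(self.deletions):
                fh.write(f"consensus\t{d.start}\t{d.end}\tdel{i}\t{d.carrier_fraction:.4f}\n")
        with open(outdir / "hrs.bed", "w") as fh:
            for i, (s, e) in enumerate(self.hr_intervals):
                fh.write(f"consensus\t{s}\t{e}\thr{i + 1}\n")


# ---------------------------------------------------------------------------
# population spec
# ---------------------------------------------------------------------------

@dataclass
class DeletionSpec:
    genome_fraction: float = 0.25
    anchor_mode: str = "hr_pairs"  # or "uniform"
    min_size: int = 2000
    max_size: int = 8000
    n_deletions: int = 2


@dataclass
class PopulationSpec:
    """Structure of the simulated genome population.

    Defaults describe the study conditions this package targets, scaled to a
    20 kb genome: four SNP frequency classes with means near 0.27%, 9.3%, 19%
    and 35%, five hr-like repeat regions, and a quarter of the genomes
    carrying one multi-kb deletion anchored at hr pairs.
    """

    genome_length: int = 20_000
    at_fraction: float = 0.593
    # (position, repeat_unit_length, unit_count) per hr
    hr_layout: list[tuple[int, int, int]] = field(
        default_factory=lambda: [
            (2_000, 70, 4),
            (6_000, 70, 6),
            (9_500, 70, 9),
            (13_000, 70, 5),
            (17_000, 70, 4),
        ]
    )
    # (locus_count, mean_frequency, frequency_sd) per class
    snp_classes: list[tuple[int, float, float]] = field(
        default_factory=lambda: [
            (50, 0.0027, 0.0015),
            (50, 0.093, 0.02),
            (50, 0.19, 0.03),
            (50, 0.35, 0.04),
        ]
    )
    deletion_spec: DeletionSpec = field(default_factory=DeletionSpec)
    circular: bool = True
    seed: int = 0
    # optional haplotype linkage: list of (class_index, block_size) is overkill
    # for current needs; linked blocks are set directly on HaplotypeSet.variants.

    def hr_intervals(self) -> list[tuple[int, int]]:
        return [(p, p + ul * uc) for p, ul, uc in self.hr_layout]

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigurationError("genome_length must be at least 1 kb")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ConfigurationError("at_fraction must lie in [0,1]")
        ivs = sorted(self.hr_intervals())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ConfigurationError("hr intervals must not overlap")
        for s, e in ivs:
            if e > self.genome_length:
                raise ConfigurationError("hr interval outside genome")
        for count, mean, sd in self.snp_classes:
            if count < 0:
                raise ConfigurationError("locus counts must be >= 0")
            if not 0.0 < mean < 1.0:
                raise ConfigurationError("class mean frequencies must lie in (0,1)")
            if sd < 0:
                raise ConfigurationError("frequency_sd must be >= 0")
        ds = self.deletion_spec
        if not 0.0 <= ds.genome_fraction < 1.0:
            raise ConfigurationError("deletion genome_fraction must lie in [0,1)")
        if ds.anchor_mode not in ("hr_pairs", "uniform"):
            raise ConfigurationError(f"unknown anchor_mode {ds.anchor_mode!r}")
        if ds.genome_fraction > 0 and not ds.min_size <= ds.max_size < self.genome_length:
            raise ConfigurationError("deletion sizes must satisfy min <= max < genome_length")


def _palindromic_unit(rng: np.random.Generator, unit_len: int) -> str:
    """A repeat unit with a central palindrome, like a baculovirus hr unit."""
    flank = (unit_len - 30) // 2
    left = "".join(rng.choice(BASES, flank))
    core_half = "".join(rng.choice(BASES, 15))
    core = core_half + revcomp(core_half)
    right = "".join(rng.choice(BASES, unit_len - flank - 30))
    return (left + core + right)[:unit_len]


def build_population(spec: PopulationSpec) -> HaplotypeSet:
    """Draw a genome population (consensus + variants + deletions) from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.genome_length

    at = spec.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T
    genome = rng.choice(BASES, size=n, p=probs)
    hr_ivs = spec.hr_intervals()
    for (pos, unit_len, unit_count), (s, e) in zip(spec.hr_layout, hr_ivs):
        unit = _palindromic_unit(rng, unit_len)
        tiled = (unit * unit_count)[: e - s]
        genome[s:e] = list(tiled)
    consensus = "".join(genome)

    total_loci = sum(c for c, _, _ in spec.snp_classes)
    if total_loci > n:
        raise CapacityError(f"{total_loci} SNP loci requested on a {n} bp genome")
    loci = rng.choice(n, size=total_loci, replace=False)

    variants: list[Variant] = []
    offset = 0
    for class_idx, (count, mean, sd) in enumerate(spec.snp_classes, start=1):
        class_loci = loci[offset : offset + count]
        offset += count
        freqs = rng.normal(mean, sd, size=count)
        for _ in range(1000):
            bad = (freqs <= 0.0) | (freqs >= 1.0)
            if not bad.any():
                break
            freqs[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:  # pragma: no cover - pathological sd
            raise ConfigurationError("could not draw class frequencies inside (0,1)")
        for locus, freq in zip(class_loci, freqs):
            ref = consensus[locus]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(Variant(int(locus), ref, str(alt), float(freq), class_idx))
    variants.sort(key=lambda v: v.locus)

    deletions = _draw_deletions(spec, hr_ivs, rng)
    haps = HaplotypeSet(consensus, variants, deletions, hr_ivs, circular=spec.circular)
    haps.validate()
    return haps


def _draw_deletions(
    spec: PopulationSpec, hr_ivs: list[tuple[int, int]], rng: np.random.Generator
) -> list[Deletion]:
    ds = spec.deletion_spec
    if ds.genome_fraction <= 0 or ds.n_deletions <= 0:
        return []
    if ds.anchor_mode == "hr_pairs" and len(hr_ivs) < 2:
        raise ConfigurationError("hr_pairs anchor mode needs at least two hr intervals")

    deletions: list[Deletion] = []
    per_del = ds.genome_fraction / ds.n_deletions
    if ds.anchor_mode == "hr_pairs":
        ivs = sorted(hr_ivs)
        feasible = [
            (i, j)
            for i in range(len(ivs))
            for j in range(i + 1, len(ivs))
            if ivs[j][1] - 1 - ivs[i][0] >= ds.min_size and ivs[j][0] - ivs[i][1] + 1 <= ds.max_size
        ]
        if not feasible:
            raise ConfigurationError("no hr pair can host a deletion in the requested size range")
        # prefer distinct hr pairs so deletions are separable events
        pool = [feasible[i] for i in rng.permutation(len(feasible))]
        for d_idx in range(ds.n_deletions):
            for _attempt in range(1000):
                if d_idx < len(pool) and _attempt < 10:
                    i, j = pool[d_idx]
                else:
                    i, j = feasible[rng.integers(len(feasible))]
                start = int(rng.integers(ivs[i][0], ivs[i][1]))
                lo = max(ivs[j][0], start + ds.min_size)
                hi = min(ivs[j][1], start + ds.max_size + 1)
                if lo < hi:
                    end = int(rng.integers(lo, hi))
                    deletions.append(Deletion(start, end, per_del))
                    break
            else:  # pragma: no cover
                raise ConfigurationError("failed to place an hr-anchored deletion")
    else:
        for _ in range(ds.n_deletions):
            size = int(rng.integers(ds.min_size, ds.max_size + 1))
            start = int(rng.integers(0, spec.genome_length - size))
            deletions.append(Deletion(start, start + size, per_del))
    return deletions


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Sequencing model: 151 bp paired reads from ~260 bp inserts at Q30+."""

    read_length: int = 151
    insert_mean: int = 260
    insert_sd: float = 20.0
    coverage: float = 100.0
    substitution_error: float = 1e-3
    high_q: int = 34
    low_q: int = 20
    low_q_run_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        if self.read_length <= 0 or self.insert_mean <= 0:
            raise ConfigurationError("read_length and insert_mean must be positive")
        if not 0.0 <= self.substitution_error < 1.0:
            raise ConfigurationError("substitution_error must lie in [0,1)")


@dataclass
class MateRecord:
    """One mate of a simulated pair, in consensus (reference) orientation."""

    seq: str
    qual: np.ndarray  # reference-orientation Phred values
    pos: int  # 0-based consensus position of the aligned block
    cigar: str
    reverse: bool
    read1: bool


@dataclass
class PairRecord:
    name: str
    mates: tuple[MateRecord, MateRecord]  # (left, right) by consensus coordinate
    hap_class: int  # 0 = intact genome, d+1 = carrier of deletion d
    wrapped: bool  # fragment crosses the circular origin


class SimulatedReads:
    """Container for one simulation run, with FASTQ/SAM writers."""

    def __init__(self, pairs: list[PairRecord], genome_length: int, read_length: int):
        self.pairs = pairs
        self.genome_length = genome_length
        self.read_length = read_length

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_wrapped(self) -> int:
        return sum(p.wrapped for p in self.pairs)

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for pair in self.pairs:
                for mate in pair.mates:
                    fh = f1 if mate.read1 else f2
                    seq, qual = mate.seq, mate.qual
                    if mate.reverse:  # sequencing orientation
                        seq, qual = revcomp(seq), qual[::-1]
                    qstr = "".join(chr(q + 33) for q in qual)
                    mate_no = 1 if mate.read1 else 2
                    fh.write(f"@{pair.name}/{mate_no}\n{seq}\n+\n{qstr}\n")

    def sam_header(self, reference_name: str = "consensus") -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": reference_name, "LN": self.genome_length}],
            }
        )

    def alignments(self, reference_name: str = "consensus") -> list[pysam.AlignedSegment]:
        """Ideal single-end alignments, coordinate-sorted."""
        header = self.sam_header(reference_name)
        out = []
        for pair in self.pairs:
            left, right = pair.mates
            for mate, other in ((left, right), (right, left)):
                a = pysam.AlignedSegment(header)
                a.query_name = pair.name
                flag = 0x1 | 0x2
                flag |= 0x40 if mate.read1 else 0x80
                if mate.reverse:
                    flag |= 0x10
                if other.reverse:
                    flag |= 0x20
                a.flag = flag
                a.reference_id = 0
                a.reference_start = mate.pos
                a.mapping_quality = 60
                a.cigarstring = mate.cigar
                a.query_sequence = mate.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in mate.qual)
                )
                a.next_reference_id = 0
                a.next_reference_start = other.pos
                tags = [("XC", pair.hap_class)]
                if pair.wrapped:
                    tags.append(("XW", 1))
                a.set_tags(tags)
                out.append(a)
        out.sort(key=lambda a: (a.reference_start, a.query_name, a.flag))
        return out

    def write_sam(self, path: str | Path, reference_name: str = "consensus") -> None:
        with pysam.AlignmentFile(
            str(path), "wh", header=self.sam_header(reference_name)
        ) as fh:
            for a in self.alignments(reference_name):
                fh.write(a)


def _hap_segments(a: int, b: int, hap_len: int, del_start: int, del_size: int):
    """Map haplotype interval [a,b) to consensus segments, in read order.

    The haplotype is the consensus with ``[del_start, del_start+del_size)``
    excised (del_size 0 for intact genomes); coordinates past ``hap_len`` wrap
    to the origin.
    """
    if a >= hap_len:  # interval lies entirely past the origin
        a -= hap_len
        b -= hap_len
    pieces = []
    if b <= hap_len:
        pieces.append((a, b))
    else:  # wraps the circular origin
        pieces.append((a, hap_len))
        pieces.append((0, b - hap_len))
    segments = []
    for x, y in pieces:
        if del_size and x < del_start < y:
            halves = [(x, del_start), (del_start, y)]
        else:
            halves = [(x, y)]
        for hx, hy in halves:
            shift = del_size if hx >= del_start and del_size else 0
            segments.append((hx + shift, hy + shift))
    return segments


def simulate_reads(haps: HaplotypeSet, rspec: ReadSimSpec) -> SimulatedReads:
    """Simulate paired-end reads from a genome population.

    Each pair derives from one genome drawn by class frequency (intact or
    carrier of one deletion), with fragment length ~N(insert_mean, insert_sd)
    and substitution errors i.i.d. per base. Variants are assigned to
    fragments independently (or per linkage block when set), matching a
    library in which every fragment comes from a different molecule.
    """
    haps.validate()
    rspec.validate()
    rng = np.random.default_rng(rspec.seed)
    L = len(haps.consensus)
    R = rspec.read_length
    n_pairs = int(round(L * rspec.coverage / (2 * R)))
    if n_pairs == 0:
        warnings.warn("requested coverage yields zero read pairs", stacklevel=2)
        return SimulatedReads([], L, R)

    carrier = np.array([d.carrier_fraction for d in haps.deletions])
    class_probs = np.concatenate([[1.0 - carrier.sum()], carrier])
    hap_classes = rng.choice(len(class_probs), size=n_pairs, p=class_probs)

    var_loci = np.array([v.locus for v in haps.variants], dtype=int)
    var_freq = np.array([v.frequency for v in haps.variants])
    var_alt = [v.alt for v in haps.variants]
    var_block = [v.block for v in haps.variants]

    inserts = np.maximum(
        np.rint(rng.normal(rspec.insert_mean, rspec.insert_sd, size=n_pairs)).astype(int), R
    )

    pairs: list[PairRecord] = []
    for idx in range(n_pairs):
        cls = int(hap_classes[idx])
        if cls == 0:
            del_start, del_size = L, 0
            hap_len = L
        else:
            d = haps.deletions[cls - 1]
            del_start, del_size = d.start, d.size
            hap_len = L - del_size
        insert = min(int(inserts[idx]), hap_len)
        if haps.circular:
            s = int(rng.integers(0, hap_len))
        else:
            s = int(rng.integers(0, max(hap_len - insert, 0) + 1))
        wrapped = s + insert > hap_len

        # fragment-level variant decisions (shared by both mates)
        frag_segments = _hap_segments(s, s + insert, hap_len, del_start, del_size)
        alt_at: dict[int, str] = {}
        block_draws: dict[int, float] = {}
        for cs, ce in frag_segments:
            lo, hi = np.searchsorted(var_loci, [cs, ce])
            for vi in range(lo, hi):
                blk = var_block[vi]
                if blk is None:
                    u = rng.random()
                else:
                    if blk not in block_draws:
                        block_draws[blk] = rng.random()
                    u = block_draws[blk]
                if u < var_freq[vi]:
                    alt_at[int(var_loci[vi])] = var_alt[vi]

        flip = bool(rng.random() < 0.5)  # which physical mate is read 1
        mates = []
        for mate_idx, (a, b) in enumerate(((s, s + R), (s + insert - R, s + insert))):
            segments = _hap_segments(a, b, hap_len, del_start, del_size)
            parts = []
            for cs, ce in segments:
                seg = haps.consensus[cs:ce]
                if alt_at:
                    lo, hi = np.searchsorted(var_loci, [cs, ce])
                    hit = [int(l) for l in var_loci[lo:hi] if int(l) in alt_at]
                    if hit:
                        seg_list = list(seg)
                        for locus in hit:
                            seg_list[locus - cs] = alt_at[locus]
                        seg = "".join(seg_list)
                parts.append(seg)
            seq = "".join(parts)
            if len(seq) != R:  # pragma: no cover - internal consistency guard
                raise AssertionError(
                    f"mate sequence length {len(seq)} != read length {R} "
                    f"(segments {segments})"
                )

            if rspec.substitution_error > 0:
                err_pos = np.flatnonzero(rng.random(R) < rspec.substitution_error)
                if err_pos.size:
                    seq_list = list(seq)
                    for p in err_pos:
                        seq_list[p] = str(rng.choice([b for b in "ACGT" if b != seq_list[p]]))
                    seq = "".join(seq_list)

            qual_seqorder = np.full(R, rspec.high_q, dtype=np.uint8)
            if rng.random() < rspec.low_q_run_prob:
                run_start = int(rng.integers(0, R))
                qual_seqorder[run_start:] = rspec.low_q
            reverse = mate_idx == 1  # right mate sequenced on the reverse strand
            qual = qual_seqorder[::-1].copy() if reverse else qual_seqorder

            # ideal alignment: largest consensus segment, remainder soft-clipped
            sizes = [ce - cs for cs, ce in segments]
            best = int(np.argmax(sizes))
            pre = sum(sizes[:best])
            post = R - pre - sizes[best]
            cigar = ""
            if pre:
                cigar += f"{pre}S"
            cigar += f"{sizes[best]}M"
            if post:
                cigar += f"{post}S"
            read1 = (mate_idx == 0) != flip
            mates.append(MateRecord(seq, qual, segments[best][0], cigar, reverse, read1))

        left, right = mates
        if left.pos > right.pos:
            left, right = right, left
        pairs.append(PairRecord(f"sim{idx:07d}", (left, right), cls, wrapped))
    return SimulatedReads(pairs, L, R)


def write_spec_config(spec: PopulationSpec, rspec: ReadSimSpec, path: str | Path) -> None:
    """Persist the generating parameters as a flat key=value file."""
    lines = []
    for obj, prefix in ((spec, "population"), (spec.deletion_spec, "deletion"), (rspec, "reads")):
        for f in dataclasses.fields(obj):
            if f.name == "deletion_spec":
                continue
            lines.append(f"{prefix}.{f.name}={getattr(obj, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")
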