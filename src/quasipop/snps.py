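"""Low-frequency SNP detection from deep pileups.

A non-consensus base is called at a position when its frequency against the
full column depth strictly exceeds the noise floor (default 2.5e-4) and, with
the default policy, when it is seen on both strands and on both mates of at
least one pair each — the support filters that separate genuine
low-frequency variation from sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .errors import MalformedInputError
from .pileup import Pileup

BASES = "ACGT"


@dataclass
class CallPolicy:
    """Frequency threshold and read-support requirements for SNP calls."""

    min_frequency: float = 2.5e-4  # strict >
    require_both_strands: bool = True
    require_both_mates: bool = True
    # "per_base": each alternate base must individually clear min_frequency.
    # "total": a position qualifies when the summed alternate frequency clears
    # a coarser floor (the ">1e-3 for all possible changes" variant); emitted
    # records are still per alternate base.
    mode: str = "per_base"
    total_min_frequency: float = 1e-3

    def validate(self) -> None:
        if not 0.0 < self.min_frequency < 1.0:
            raise ValueError("min_frequency must lie in (0,1)")
        if self.mode not in ("per_base", "total"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SnpRecord:
    position: int
    consensus_base: str
    alt_base: str
    alt_count: int
    depth: int
    frequency: float
    fwd_support: bool
    rev_support: bool
    mate_pair_support: bool
    cluster: int | None = None


def call_snps(
    pileup: Pileup, consensus: str, policy: CallPolicy | None = None
) -> list[SnpRecord]:
    """Emit one record per (position, alternate base) passing all filters."""
    policy = policy or CallPolicy()
    policy.validate()
    if len(consensus) != pileup.consensus_length:
        raise MalformedInputError(
            f"consensus length {len(consensus)} != pileup length {pileup.consensus_length}"
        )
    counts = pileup.counts  # (L, 4)
    depth = counts.sum(axis=1)
    cons_code = np.frombuffer(consensus.upper().encode(), dtype=np.uint8)
    cons_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), cons_code)
    # positions with non-ACGT consensus never emit
    cons_valid = np.isin(cons_code, np.frombuffer(b"ACGT", dtype=np.uint8))

    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth[:, None] > 0, counts / np.maximum(depth, 1)[:, None], 0.0)

    is_alt = np.ones_like(counts, dtype=bool)
    rows = np.arange(len(consensus))
    safe_idx = np.where(cons_valid, cons_idx, 0)
    is_alt[rows, safe_idx] = ~cons_valid  # consensus base is never its own alternate
    is_alt &= cons_valid[:, None]

    if policy.mode == "per_base":
        passes = freq > policy.min_frequency
    else:
        alt_total = np.where(is_alt, counts, 0).sum(axis=1)
        pos_pass = alt_total > policy.total_min_frequency * np.maximum(depth, 1)
        passes = pos_pass[:, None] & (counts > 0)
    mask = is_alt & passes & (depth > 0)[:, None]

    fwd_ok = pileup.arr[1] > 0
    rev_ok = pileup.arr[2] > 0
    m1_ok = pileup.arr[3] > 0
    m2_ok = pileup.arr[4] > 0
    if policy.require_both_strands:
        mask &= fwd_ok & rev_ok
    if policy.require_both_mates:
        mask &= m1_ok & m2_ok

    records = []
    for pos, base_idx in zip(*np.nonzero(mask)):
        records.append(
            SnpRecord(
                position=int(pos),
                consensus_base=consensus[pos],
                alt_base=BASES[base_idx],
                alt_count=int(counts[pos, base_idx]),
                depth=int(depth[pos]),
                frequency=float(counts[pos, base_idx] / depth[pos]),
                fwd_support=bool(fwd_ok[pos, base_idx]),
                rev_support=bool(rev_ok[pos, base_idx]),
                mate_pair_support=bool(m1_ok[pos, base_idx] and m2_ok[pos, base_idx]),
            )
        )
    return records


def snps_to_frame(snps: Iterable[SnpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": s.position,
                "consensus_base": s.consensus_base,
                "alt_base": s.alt_base,
                "alt_count": s.alt_count,
                "depth": s.depth,
                "frequency": s.frequency,
                "fwd_support": s.fwd_support,
                "rev_support": s.rev_support,
                "mate_pair_support": s.mate_pair_support,
                "cluster": s.cluster,
            }
            for s in snps
        ]
    )


def write_snp_tsv(snps: Iterable[SnpRecord], path: str | Path) -> None:
    snps_to_frame(snps).to_csv(path, sep="\t", index=False)


def write_snp_vcf(
    snps: Iterable[SnpRecord], path: str | Path, reference_name: str = "consensus",
    reference_length: int | None = None,
) -> None:
    """Write calls as VCF with the consensus base as REF and AF in INFO."""
    header = pysam.VariantHeader()
    header.add_line('##source=quasipop')
    if reference_length is not None:
        header.contigs.add(reference_name, length=reference_length)
    else:
        header.contigs.add(reference_name)
    header.info.add("AF", "A", "Float", "Alternate allele frequency in the population")
    header.info.add("DP", "1", "Integer", "Pileup depth at the locus")
    header.info.add("CLUSTER", "A", "Integer", "Frequency-class cluster label")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(snps, key=lambda r: (r.position, r.alt_base)):
            rec = out.new_record(
                contig=reference_name,
                start=s.position,
                stop=s.position + 1,
                alleles=(s.consensus_base, s.alt_base),
            )
            rec.info["AF"] = (s.frequency,)
            rec.info["DP"] = s.depth
            if s.cluster is not None:
                rec.info["CLUSTER"] = (s.cluster,)
            out.write(rec)


@dataclass(frozen=True)
class LinkedPair:
    """Co-observation of two SNP loci on single sequenced fragments."""

    locus_a: int
    locus_b: int
    covering_fragments: int
    co_occurrences: int
    expected_independent: float


def linked_within_insert(
    snps: list[SnpRecord],
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    max_distance: int = 260,
) -> list[LinkedPair]:
    """Count co-occurrence of SNP alternate alleles on the same fragment.

    Only locus pairs at most ``max_distance`` apart are reported: beyond the
    insert size single fragments cannot link two loci, so no inference is
    attempted there. The expected count under independence is
    f_a * f_b * covering fragments.
    """
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            return linked_within_insert(snps, list(fh), max_distance)

    by_locus = {s.position: s for s in snps}
    loci = np.array(sorted(by_locus), dtype=int)
    # per locus: fragment -> observed base (mates must agree, else dropped)
    obs: dict[int, dict[str, str | None]] = {int(l): {} for l in loci}
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        ap_start, ap_end = aln.reference_start, aln.reference_end
        lo, hi = np.searchsorted(loci, [ap_start, ap_end])
        if lo == hi:
            continue
        ref_to_q = {r: q for q, r in aln.get_aligned_pairs(matches_only=True)}
        for locus in loci[lo:hi]:
            q = ref_to_q.get(int(locus))
            if q is None:
                continue
            base = aln.query_sequence[q]
            frag = obs[int(locus)]
            prev = frag.get(aln.query_name)
            if prev is None:
                frag[aln.query_name] = base
            elif prev != base:
                frag[aln.query_name] = None  # mates disagree: discard
    out = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = int(loci[i]), int(loci[j])
            if b - a > max_distance:
                break
            obs_a, obs_b = obs[a], obs[b]
            shared = [
                f
                for f in obs_a.keys() & obs_b.keys()
                if obs_a[f] is not None and obs_b[f] is not None
            ]
            if not shared:
                continue
            alt_a, alt_b = by_locus[a].alt_base, by_locus[b].alt_base
            co = sum(1 for f in shared if obs_a[f] == alt_a and obs_b[f] == alt_b)
            fa = sum(1 for f in shared if obs_a[f] == alt_a) / len(shared)
            fb = sum(1 for f in shared if obs_b[f] == alt_b) / len(shared)
            out.append(LinkedPair(a, b, len(shared), co, fa * fb * len(shared)))
    return out
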