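"""Base-quality trimming and native per-position pileup construction.

The quality rule keeps, per read, the longest maximal run of bases at or
above a Phred floor, and rejects the read outright when that run is shorter
than a minimum length (default: 100 consecutive bases at Q>=30). Retained
bases are mapped through the CIGAR onto consensus coordinates and counted
per base, per strand and per mate index.

Counting is read-based by default. With ``dedup_overlaps=True`` the overlap
between the two mates of a pair is counted once (the first mate's call wins),
so each sequenced fragment contributes at most one observation per position —
the same convention samtools mpileup applies by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import MalformedInputError

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass
class QcPolicy:
    """Read-level base quality filter."""

    min_phred: int = 30
    min_run: int = 100

    def validate(self) -> None:
        if not 0 <= self.min_phred <= 60:
            raise ValueError("min_phred must lie in [0, 60]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def trim_read(qualities: Sequence[int], policy: QcPolicy | None = None) -> tuple[int, int] | None:
    """Longest run of bases with Phred >= min_phred, or None if below min_run.

    Returns the kept interval ``[start, end)`` in read coordinates; ties are
    broken toward the leftmost run. Rejection is a value, not an error.
    """
    policy = policy or QcPolicy()
    policy.validate()
    q = np.asarray(qualities)
    if q.size == 0:
        raise ValueError("empty quality sequence")
    ok = q >= policy.min_phred
    if not ok.any():
        return None
    # run boundaries of the boolean mask
    padded = np.concatenate([[False], ok, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax returns the leftmost maximum
    if lengths[best] < policy.min_run:
        return None
    return int(starts[best]), int(ends[best])


@dataclass
class PileupColumn:
    """Per-position counts split by base, strand and mate index."""

    position: int
    counts: np.ndarray  # (4,) A,C,G,T
    fwd_counts: np.ndarray
    rev_counts: np.ndarray
    mate1_counts: np.ndarray
    mate2_counts: np.ndarray

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


class Pileup:
    """Dense pileup over a consensus of known length."""

    LAYERS = ("total", "fwd", "rev", "mate1", "mate2")

    def __init__(self, consensus_length: int):
        self.consensus_length = consensus_length
        self.arr = np.zeros((5, consensus_length, 4), dtype=np.int64)
        self.n_reads_retained = 0
        self.n_reads_rejected = 0

    @property
    def counts(self) -> np.ndarray:
        return self.arr[0]

    @property
    def depth(self) -> np.ndarray:
        return self.arr[0].sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        return PileupColumn(
            position,
            self.arr[0, position],
            self.arr[1, position],
            self.arr[2, position],
            self.arr[3, position],
            self.arr[4, position],
        )

    def __iter__(self):
        for pos in range(self.consensus_length):
            yield self.column(pos)

    def to_frame(self) -> pd.DataFrame:
        cols = {"position": np.arange(self.consensus_length), "depth": self.depth}
        for li, layer in enumerate(self.LAYERS):
            prefix = "" if layer == "total" else f"{layer}_"
            for b, bi in BASE_INDEX.items():
                cols[f"{prefix}{b}"] = self.arr[li, :, bi]
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _match_blocks(aln: pysam.AlignedSegment, keep: tuple[int, int]):
    """Retained (ref_start, ref_end, query_start) match blocks after trimming."""
    t0, t1 = keep
    qpos, rpos = 0, aln.reference_start
    blocks = []
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            lo = max(qpos, t0)
            hi = min(qpos + length, t1)
            if lo < hi:
                blocks.append((rpos + (lo - qpos), rpos + (hi - qpos), lo))
            qpos += length
            rpos += length
        elif op == 1 or op == 4:  # I, S consume query only
            qpos += length
        elif op == 2 or op == 3:  # D, N consume reference only
            rpos += length
        else:
            raise MalformedInputError(
                f"read {aln.query_name}: unsupported CIGAR op {op}"
            )
    return blocks


def _add_blocks(pileup: Pileup, blocks, codes: np.ndarray, layers: tuple[int, ...]) -> None:
    for rs, re_, qs in blocks:
        idx = np.arange(rs, re_)
        base = codes[qs : qs + (re_ - rs)]
        valid = base >= 0
        if not valid.all():
            idx, base = idx[valid], base[valid]
        for li in layers:
            np.add.at(pileup.arr[li], (idx, base), 1)


def _clip_blocks(blocks, spans):
    """Remove parts of match blocks whose reference interval lies in any span."""
    if not spans:
        return blocks
    out = blocks
    for cs, ce in spans:
        nxt = []
        for rs, re_, qs in out:
            if re_ <= cs or rs >= ce:
                nxt.append((rs, re_, qs))
                continue
            if rs < cs:
                nxt.append((rs, cs, qs))
            if re_ > ce:
                nxt.append((ce, re_, qs + (ce - rs)))
        out = nxt
    return out


def build_pileup(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    consensus_length: int,
    policy: QcPolicy | None = None,
    dedup_overlaps: bool = False,
) -> Pileup:
    """Build a per-position pileup from SAM/BAM alignments.

    Only bases inside each read's retained quality interval are counted;
    soft-clipped bases never count. ``dedup_overlaps`` collapses the
    mate-overlap region of a pair to a single observation per position.
    """
    policy = policy or QcPolicy()
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            return build_pileup(list(fh), consensus_length, policy, dedup_overlaps)

    pileup = Pileup(consensus_length)
    pending: dict[str, list] = {}
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if aln.reference_end is not None and aln.reference_end > consensus_length:
            raise MalformedInputError(
                f"read {aln.query_name} aligns past the consensus end "
                f"({aln.reference_end} > {consensus_length})"
            )
        quals = aln.query_qualities
        if quals is None:
            raise MalformedInputError(f"read {aln.query_name} lacks base qualities")
        keep = trim_read(quals, policy)
        if keep is None:
            pileup.n_reads_rejected += 1
            continue
        pileup.n_reads_retained += 1
        blocks = _match_blocks(aln, keep)
        codes = _BASE_CODE[np.frombuffer(aln.query_sequence.encode(), dtype=np.uint8)]
        strand_layer = 2 if aln.is_reverse else 1
        mate_layer = 4 if aln.is_read2 else 3

        if dedup_overlaps and aln.is_paired:
            if aln.query_name in pending:
                first_blocks, _, _ = pending.pop(aln.query_name)
                spans = [(rs, re_) for rs, re_, _ in first_blocks]
                blocks = _clip_blocks(blocks, spans)
            else:
                pending[aln.query_name] = (blocks, codes, None)
        _add_blocks(pileup, blocks, codes, (0, strand_layer, mate_layer))
    return pileup
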