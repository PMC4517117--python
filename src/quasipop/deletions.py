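"""Large-deletion delimitation from single-end remapped pair distances.

With a 260 bp insert and 151 bp reads, properly mapped mates overlap by
about 42 nt, i.e. the expected inner gap (right mate start minus left mate
end) is about -42. A pair whose mates map much farther apart derives from a
genome carrying a deletion between them; the implied deletion size is the
inner gap minus the expected inner gap. The scan ranks all pairs by inner
gap, keeps the most distant fraction (5% and, with a minimum-gap exclusion
that removes pure repeat-length artifacts, 2.81%), profiles their coverage
to reveal hotspots, merges the bracketed intervals into deletion calls, and
anchors call endpoints on homologous repeat regions (hrs).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binomtest

from .errors import ConfigurationError, MalformedInputError

EXPECTED_INNER_GAP = -42  # 260 bp insert, 2 x 151 bp reads


@dataclass(frozen=True)
class PairGap:
    """Mapped coordinates of a read pair and the gap they imply."""

    pair_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    inner_gap: int
    implied_deletion: int


@dataclass
class GapExclusions:
    unmapped: int = 0
    multimapped: int = 0
    wrapped: int = 0
    unpaired: int = 0


def compute_pair_gaps(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    expected_inner_gap: int = EXPECTED_INNER_GAP,
) -> tuple[list[PairGap], GapExclusions]:
    """Reinstate pair identity over single-end alignments and measure gaps.

    Pairs with an unmapped mate, secondary/supplementary (multi-mapped)
    evidence, or flagged as wrapping the circular origin (XW tag) are
    excluded and counted.
    """
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            return compute_pair_gaps(list(fh), expected_inner_gap)

    excl = GapExclusions()
    mates: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    dropped: dict[str, str] = {}
    for aln in alignments:
        name = aln.query_name
        if aln.is_secondary or aln.is_supplementary:
            dropped[name] = "multimapped"
            continue
        if aln.is_unmapped:
            dropped[name] = "unmapped"
            continue
        if aln.has_tag("XW"):
            dropped.setdefault(name, "wrapped")
            continue
        mates[name].append(aln)
    for reason in dropped.values():
        setattr(excl, reason, getattr(excl, reason) + 1)

    gaps: list[PairGap] = []
    for name in sorted(mates):
        if name in dropped:
            continue
        group = mates[name]
        if len(group) == 1:
            excl.unpaired += 1
            continue
        if len(group) > 2:
            raise MalformedInputError(f"pair {name} has {len(group)} primary alignments")
        a, b = group
        if a.is_read1 == b.is_read1 and (
            (a.reference_start, a.reference_end) != (b.reference_start, b.reference_end)
        ):
            raise MalformedInputError(f"pair {name} has conflicting duplicate mates")
        left, right = sorted(group, key=lambda x: (x.reference_start, x.reference_end))
        inner = right.reference_start - left.reference_end
        gaps.append(
            PairGap(
                name,
                left.reference_start,
                left.reference_end,
                right.reference_start,
                right.reference_end,
                int(inner),
                int(inner - expected_inner_gap),
            )
        )
    return gaps, excl


@dataclass
class TailSelection:
    """The most-distant fraction of pairs, optionally with a minimum-gap cut."""

    fraction: float
    min_gap_exclusion: int | None
    selected: list[PairGap]
    cut_gap: int  # smallest inner gap that made the pre-exclusion tail


def select_tail(
    gaps: list[PairGap],
    fraction: float = 0.05,
    min_gap_exclusion: int | None = None,
) -> TailSelection:
    """Rank pairs by inner gap descending and keep the top fraction.

    Ties at the cut are broken stably by input order. With
    ``min_gap_exclusion`` set (e.g. 669, the largest hr length), selected
    pairs with inner gap <= that value are additionally dropped, removing
    pairs that merely delete repeat units within a single hr.
    """
    if not gaps:
        raise ConfigurationError("select_tail needs a non-empty gap list")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("tail fraction must lie in (0,1)")
    k = math.ceil(fraction * len(gaps))
    order = sorted(range(len(gaps)), key=lambda i: (-gaps[i].inner_gap, i))
    chosen = [gaps[i] for i in order[:k]]
    cut = chosen[-1].inner_gap
    if min_gap_exclusion is not None:
        chosen = [g for g in chosen if g.inner_gap > min_gap_exclusion]
    return TailSelection(fraction, min_gap_exclusion, chosen, cut)


def deletion_coverage_profile(
    selection: TailSelection,
    genome_length: int,
    peak_factor: float = 5.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Coverage of the genome by the selected pairs' mates, plus peak intervals.

    Peaks are maximal runs of positions whose coverage exceeds
    ``peak_factor`` times the track median (track mean when the median is 0).
    """
    if not selection.selected:
        raise ConfigurationError("empty tail selection")
    cov = np.zeros(genome_length, dtype=np.int64)
    for g in selection.selected:
        cov[g.left_start : g.left_end] += 1
        cov[g.right_start : g.right_end] += 1
    base = float(np.median(cov))
    if base == 0:
        base = float(cov.mean())
    thr = peak_factor * base
    above = cov > thr
    peaks = []
    if above.any():
        padded = np.concatenate([[False], above, [False]])
        diff = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            peaks.append((int(s), int(e)))
    return cov, peaks


@dataclass
class DeletionCall:
    start: int
    end: int
    support: int
    boundary_uncertainty: float
    left_anchor_hr: str | None = None
    right_anchor_hr: str | None = None
    member_starts: list[int] = field(default_factory=list, repr=False)
    member_ends: list[int] = field(default_factory=list, repr=False)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def call_deletions(
    selection: TailSelection,
    min_support: int = 5,
    merge_slop: int = 0,
) -> list[DeletionCall]:
    """Merge bracketed intervals of selected pairs into deletion calls.

    Each selected pair with a positive inner gap proposes the interval
    (left mate end, right mate start); intervals with >= 50% reciprocal
    overlap against a growing cluster's median interval are merged. The call
    boundary is the median of member endpoints; the uncertainty is the larger
    endpoint interquartile range. Calls below ``min_support`` are dropped.
    """
    cands = sorted(
        ((g.left_end, g.right_start) for g in selection.selected if g.inner_gap > 0),
        key=lambda iv: iv,
    )
    clusters: list[list[tuple[int, int]]] = []
    reps: list[tuple[int, int]] = []
    for iv in cands:
        placed = False
        probe = (iv[0] - merge_slop, iv[1] + merge_slop)
        for ci in range(len(clusters)):
            if _reciprocal_overlap(probe, reps[ci]) >= 0.5:
                clusters[ci].append(iv)
                starts = [x[0] for x in clusters[ci]]
                ends = [x[1] for x in clusters[ci]]
                reps[ci] = (int(np.median(starts)), int(np.median(ends)))
                placed = True
                break
        if not placed:
            clusters.append([iv])
            reps.append(iv)
    calls = []
    for members, rep in zip(clusters, reps):
        if len(members) < min_support:
            continue
        starts = np.array([m[0] for m in members])
        ends = np.array([m[1] for m in members])
        iqr = max(
            float(np.subtract(*np.percentile(starts, [75, 25]))),
            float(np.subtract(*np.percentile(ends, [75, 25]))),
        )
        calls.append(
            DeletionCall(
                start=int(np.median(starts)),
                end=int(np.median(ends)),
                support=len(members),
                boundary_uncertainty=iqr,
                member_starts=starts.tolist(),
                member_ends=ends.tolist(),
            )
        )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


def hr_anchoring(
    calls: list[DeletionCall],
    hr_intervals: list[tuple[int, int]] | list[tuple[int, int, str]],
    anchor_slop: int = 50,
) -> list[DeletionCall]:
    """Flag call endpoints that fall inside an hr interval (+/- slop)."""
    named = []
    for i, iv in enumerate(hr_intervals):
        if len(iv) == 3:
            named.append((int(iv[0]), int(iv[1]), str(iv[2])))
        else:
            named.append((int(iv[0]), int(iv[1]), f"hr{i + 1}"))
    named.sort()
    for s, e in zip(named, named[1:]):
        if e[0] < s[1]:
            raise ConfigurationError("hr intervals must be non-overlapping")

    def find(pos: int) -> str | None:
        for s, e, name in named:
            if s - anchor_slop <= pos < e + anchor_slop:
                return name
        return None

    for call in calls:
        call.left_anchor_hr = find(call.start)
        call.right_anchor_hr = find(call.end)
    return calls


def deleted_fraction(
    gaps: list[PairGap], min_deletion: int
) -> tuple[float, tuple[float, float]]:
    """Fraction of pairs implying a deletion larger than ``min_deletion``.

    A pair-level estimator of the genome-level deleted fraction, reported
    with a binomial (Clopper-Pearson) 95% interval. For an unbiased estimate
    restrict ``gaps`` to pairs whose fragment window brackets a candidate
    junction.
    """
    if not gaps:
        raise ConfigurationError("deleted_fraction needs a non-empty gap list")
    k = sum(1 for g in gaps if g.implied_deletion > min_deletion)
    n = len(gaps)
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return k / n, (float(ci.low), float(ci.high))


def gap_histogram(gaps: list[PairGap], bin_width: int = 10) -> pd.DataFrame:
    """Histogram of inner gaps as a tidy frame (bin_start, bin_end, count)."""
    inner = np.array([g.inner_gap for g in gaps])
    lo = int(np.floor(inner.min() / bin_width) * bin_width)
    hi = int(np.ceil((inner.max() + 1) / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(inner, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def write_calls_bed(calls: list[DeletionCall], path: str | Path, chrom: str = "consensus") -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(f"{chrom}\t{c.start}\t{c.end}\tdel_call_{i}\t{c.support}\n")


def write_calls_tsv(calls: list[DeletionCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start": c.start,
                "end": c.end,
                "support": c.support,
                "boundary_uncertainty": c.boundary_uncertainty,
                "left_anchor_hr": c.left_anchor_hr or "",
                "right_anchor_hr": c.right_anchor_hr or "",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_coverage_bedgraph(
    cov: np.ndarray, path: str | Path, chrom: str = "consensus"
) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="deletion_read_coverage"\n')
        # run-length encode
        change = np.flatnonzero(np.diff(cov)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(cov)]])
        for s, e in zip(starts, ends):
            if cov[s]:
                fh.write(f"{chrom}\t{s}\t{e}\t{int(cov[s])}\n")
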