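"""Per-position Tajima's D from deep pileups, and subset comparisons.

At a single position covered by ``n`` reads, the reads are treated as the
sample of sequences. Mean pairwise diversity pi is the probability two
distinct reads differ at the site; Watterson's estimator is S/a1 with
S in {0, 1}: the site is segregating when at least two bases exceed the
noise-floor frequency. D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)); with
S <= 1 the S*(S-1) term vanishes. Sites with S = 0 have undefined D and are
excluded from genome summaries (optionally counted as 0 by flag).

The n-dependent constants (a1, a2, b1, b2, c1, c2, e1, e2) follow Tajima's
variance-normalisation; harmonic sums are evaluated through the digamma and
trigamma functions, which keeps them exact to machine precision for read
depths into the millions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateInputError
from .pileup import Pileup

_EULER_GAMMA = float(np.euler_gamma)
_ZETA2 = float(np.pi**2 / 6)


@dataclass
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n) -> TajimaConstants | dict[str, np.ndarray]:
    """Tajima's n-dependent constants; accepts a scalar or an array of depths.

    a1 = sum_{i<n} 1/i and a2 = sum_{i<n} 1/i^2 are computed via
    digamma/trigamma: a1 = psi(n) + gamma, a2 = zeta(2) - psi'(n).
    """
    scalar = np.isscalar(n)
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if (n_arr < 2).any():
        raise DegenerateInputError("Tajima constants need n >= 2")
    a1 = special.digamma(n_arr) + _EULER_GAMMA
    a2 = _ZETA2 - special.polygamma(1, n_arr)
    b1 = (n_arr + 1) / (3 * (n_arr - 1))
    b2 = 2 * (n_arr**2 + n_arr + 3) / (9 * n_arr * (n_arr - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n_arr + 2) / (a1 * n_arr) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if scalar:
        return TajimaConstants(
            int(n), *(float(v[0]) for v in (a1, a2, b1, b2, c1, c2, e1, e2))
        )
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_pi(base_counts) -> float:
    """Mean pairwise difference at one site: fraction of differing read pairs."""
    c = np.asarray(base_counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise DegenerateInputError("site_pi needs at least two reads")
    return float((n * n - (c * c).sum()) / (n * (n - 1)))


@dataclass
class TajimaSite:
    position: int
    n: int
    segregating: bool
    pi: float
    theta_w: float
    d: float  # NaN when undefined (S = 0)


def site_tajima_d(base_counts, noise_floor: float = 2.5e-4, position: int = -1) -> TajimaSite:
    """Tajima's D at one site from base counts (requires depth >= 4)."""
    c = np.asarray(base_counts, dtype=float)
    n = int(c.sum())
    if n < 4:
        raise DegenerateInputError("site Tajima's D needs depth >= 4")
    pi = site_pi(c)
    seg = int((c / n > noise_floor).sum()) >= 2
    k = tajima_constants(n)
    theta_w = (1.0 / k.a1) if seg else 0.0
    if not seg:
        return TajimaSite(position, n, False, pi, theta_w, float("nan"))
    d = (pi - theta_w) / np.sqrt(k.e1)  # S=1: the S(S-1) variance term vanishes
    return TajimaSite(position, n, True, pi, theta_w, float(d))


def genome_tajima_d(
    pileup: Pileup,
    noise_floor: float = 2.5e-4,
    subsample_n: int | None = None,
    undefined_as_zero: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-position Tajima's D over a whole pileup (vectorised).

    Sites with depth < 4 are skipped. ``subsample_n`` optionally downsamples
    every column to a common depth (without replacement), making D values
    comparable across positions of unequal coverage.
    """
    counts = pileup.counts.astype(np.int64)
    if subsample_n is not None:
        counts = _subsample_counts(counts, subsample_n, seed)
    depth = counts.sum(axis=1)
    ok = depth >= 4
    c = counts[ok].astype(float)
    n = depth[ok].astype(float)
    pi = (n * n - (c * c).sum(axis=1)) / (n * (n - 1))
    seg = ((c / n[:, None]) > noise_floor).sum(axis=1) >= 2
    k = tajima_constants(n)
    theta_w = np.where(seg, 1.0 / k["a1"], 0.0)
    with np.errstate(invalid="ignore"):
        d = np.where(seg, (pi - theta_w) / np.sqrt(k["e1"]), np.nan)
    if undefined_as_zero:
        d = np.where(seg, d, 0.0)
    return pd.DataFrame(
        {
            "position": np.flatnonzero(ok),
            "n": depth[ok],
            "segregating": seg,
            "pi": pi,
            "theta_w": theta_w,
            "D": d,
        }
    )


def _subsample_counts(counts: np.ndarray, target_n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for i, row in enumerate(counts):
        n = row.sum()
        if n <= target_n:
            out[i] = row
            continue
        drawn = rng.multivariate_hypergeometric(row, target_n)
        out[i] = drawn
    return out


@dataclass
class SelectionSummary:
    genome_mean_d: float
    genome_sd_d: float
    subset_mean_d: float
    subset_sd_d: float
    welch_t: float
    welch_df: float
    welch_p: float


def welch_test(group1, group2) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df and two-sided p for two samples."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise DegenerateInputError("Welch test needs at least two values per group")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_subsets(all_d: pd.DataFrame, subset_loci) -> SelectionSummary:
    """Welch two-sample t-test of subset D values against the rest of the genome.

    ``all_d`` is the frame from :func:`genome_tajima_d`; rows with undefined D
    are excluded from both groups.
    """
    defined = all_d.dropna(subset=["D"])
    subset_loci = np.asarray(sorted(set(subset_loci)), dtype=int)
    in_subset = defined["position"].isin(subset_loci)
    sub = defined.loc[in_subset, "D"].to_numpy()
    bg = defined.loc[~in_subset, "D"].to_numpy()
    if sub.size < 2 or bg.size < 2:
        raise DegenerateInputError("both groups need at least two defined D values")
    res = stats.ttest_ind(sub, bg, equal_var=False)
    return SelectionSummary(
        genome_mean_d=float(bg.mean()),
        genome_sd_d=float(bg.std(ddof=1)),
        subset_mean_d=float(sub.mean()),
        subset_sd_d=float(sub.std(ddof=1)),
        welch_t=float(res.statistic),
        welch_df=float(res.df),
        welch_p=float(res.pvalue),
    )


def write_bedgraph(d_frame: pd.DataFrame, path: str | Path, chrom: str = "consensus") -> None:
    defined = d_frame.dropna(subset=["D"])
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="tajima_d"\n')
        for _, row in defined.iterrows():
            p = int(row["position"])
            fh.write(f"{chrom}\t{p}\t{p + 1}\t{row['D']:.4f}\n")
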