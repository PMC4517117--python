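"""Codon effects of SNPs on annotated ORFs and amino-acid polarity classes.

SNPs are mapped onto ORF annotations (GFF), both codons are reconstructed
from the consensus (reverse-complementing minus-strand ORFs), translated
with the standard genetic code, and classified as synonymous, missense or
nonsense. Amino acids are grouped by charge and polarity — acidic-polar
(AP: D, E), basic-polar (BP: K, R, H), neutral-polar (NP: S, T, C, N, Q, Y)
and non-polar (G, A, V, L, I, P, F, M, W); a stop codon has no class. A SNP
whose substitution moves the residue between classes is flagged as
polarity-changing. The mapping for W, F and V follows the standard scheme;
they do not occur among the observed changes bundled as reference data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError, MalformedInputError
from .snps import SnpRecord

AP = "AP"
BP = "BP"
NP = "NP"
NO_POLARITY = "NoPolarity"
STOP_CLASS = "None"

_POLARITY = {
    **{aa: AP for aa in "DE"},
    **{aa: BP for aa in "KRH"},
    **{aa: NP for aa in "STCNQY"},
    **{aa: NO_POLARITY for aa in "GAVLIPFMW"},
    "*": STOP_CLASS,
}


def polarity_class(aa: str) -> str:
    """Charge-and-polarity class of an amino acid (or '*' for stop)."""
    try:
        return _POLARITY[aa.upper() if aa != "*" else aa]
    except KeyError:
        raise MalformedInputError(f"unknown amino acid symbol {aa!r}") from None


@dataclass(frozen=True)
class OrfAnnotation:
    name: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'

    def validate(self, genome_length: int | None = None) -> None:
        if (self.end - self.start) % 3 != 0:
            raise MalformedInputError(f"ORF {self.name} length not a multiple of 3")
        if self.strand not in "+-":
            raise MalformedInputError(f"ORF {self.name} has invalid strand {self.strand!r}")
        if genome_length is not None and not (0 <= self.start < self.end <= genome_length):
            raise MalformedInputError(f"ORF {self.name} outside genome")


@dataclass(frozen=True)
class CodonEffect:
    orf: str
    codon_index: int
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    effect: str  # synonymous | missense | nonsense
    polarity_before: str
    polarity_after: str
    polarity_changed: bool


def codon_pair_effect(codon_before: str, codon_after: str, orf: str = "", codon_index: int = -1) -> CodonEffect:
    """Effect of a single-codon substitution, including polarity classes."""
    cb, ca = codon_before.upper(), codon_after.upper()
    if len(cb) != 3 or len(ca) != 3:
        raise MalformedInputError("codons must be trinucleotides")
    diffs = sum(x != y for x, y in zip(cb, ca))
    if diffs != 1:
        raise MalformedInputError(f"codons {cb}->{ca} differ at {diffs} bases, expected 1")
    aa_b = str(Seq(cb).translate())
    aa_a = str(Seq(ca).translate())
    if aa_a == aa_b:
        effect = "synonymous"
    elif aa_a == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    pb, pa = polarity_class(aa_b), polarity_class(aa_a)
    return CodonEffect(orf, codon_index, cb, ca, aa_b, aa_a, effect, pb, pa, pb != pa)


def snp_codon_effect(
    snp: SnpRecord, orfs: Iterable[OrfAnnotation], consensus: str
) -> list[CodonEffect]:
    """Codon effect(s) of one SNP; one entry per overlapping ORF.

    Returns an empty list for non-coding SNPs. Minus-strand ORFs are handled
    by reverse-complementing the codon and the substituting base.
    """
    out = []
    for orf in orfs:
        orf.validate(len(consensus))
        if not orf.start <= snp.position < orf.end:
            continue
        if orf.strand == "+":
            offset = snp.position - orf.start
        else:
            offset = orf.end - 1 - snp.position
        codon_index = offset // 3
        within = offset % 3
        if orf.strand == "+":
            cstart = orf.start + codon_index * 3
            codon_before = consensus[cstart : cstart + 3]
            alt = snp.alt_base
        else:
            cend = orf.end - codon_index * 3
            codon_before = str(Seq(consensus[cend - 3 : cend]).reverse_complement())
            alt = str(Seq(snp.alt_base).reverse_complement())
        codon_after = codon_before[:within] + alt + codon_before[within + 1 :]
        if codon_before[within] == alt:
            raise MalformedInputError(
                f"SNP at {snp.position} does not change the codon in ORF {orf.name}"
            )
        out.append(codon_pair_effect(codon_before, codon_after, orf.name, codon_index))
    return out


def tss_distance(snp_position: int, tss_positions: list[tuple[int, str]]) -> tuple[int, str]:
    """Distance to the nearest transcription start site, with its gene label."""
    if not tss_positions:
        raise ConfigurationError("tss_distance needs at least one TSS")
    best = min(tss_positions, key=lambda t: (abs(t[0] - snp_position), t[0]))
    return abs(best[0] - snp_position), best[1]


@dataclass
class PolarityCensus:
    coding: int
    non_synonymous: int
    polarity_changing: int
    per_gene: pd.DataFrame


def polarity_change_census(effects: Iterable[CodonEffect]) -> PolarityCensus:
    """Tally coding, non-synonymous and polarity-changing effects, per gene."""
    rows = [
        {
            "gene": e.orf,
            "non_synonymous": e.effect != "synonymous",
            "polarity_changing": e.polarity_changed,
        }
        for e in effects
    ]
    df = pd.DataFrame(rows, columns=["gene", "non_synonymous", "polarity_changing"])
    per_gene = (
        df.groupby("gene")
        .agg(coding=("gene", "size"), non_synonymous=("non_synonymous", "sum"),
             polarity_changing=("polarity_changing", "sum"))
        .reset_index()
        if len(df)
        else pd.DataFrame(columns=["gene", "coding", "non_synonymous", "polarity_changing"])
    )
    return PolarityCensus(
        coding=len(df),
        non_synonymous=int(df["non_synonymous"].sum()) if len(df) else 0,
        polarity_changing=int(df["polarity_changing"].sum()) if len(df) else 0,
        per_gene=per_gene,
    )


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_orfs_gff(path: str | Path, feature_types: tuple[str, ...] = ("CDS", "ORF", "gene")) -> list[OrfAnnotation]:
    """Load ORF annotations from a GFF3 file (1-based closed -> 0-based half-open)."""
    orfs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"orf_{parts[3]}"
            orfs.append(
                OrfAnnotation(name, int(parts[3]) - 1, int(parts[4]), parts[6])
            )
    return orfs


def read_positions_bed(path: str | Path) -> list[tuple[int, str]]:
    """Load point features (e.g. TSS) from BED: (0-based position, label)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            label = parts[3].strip() if len(parts) > 3 else f"pos_{parts[1]}"
            out.append((int(parts[1]), label))
    return out


def read_intervals_bed(path: str | Path) -> list[tuple[int, int, str]]:
    """Load intervals (e.g. hrs) from BED: (start, end, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else f"iv_{parts[1]}"
            out.append((int(parts[1]), int(parts[2]), name))
    return out


def load_reference_polarity_changes() -> pd.DataFrame:
    """Published high-frequency polarity-changing codon substitutions observed
    in the AcMNPV-WP10 genome population (reference fixture)."""
    with resources.files("quasipop.data").joinpath("wp10_polarity_changes.tsv").open() as fh:
        # the stop-codon class is the literal string "None"
        return pd.read_csv(fh, sep="\t", dtype={"aa_to": str}, keep_default_na=False)


def effects_to_frame(effects: Iterable[CodonEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": e.orf,
                "codon_index": e.codon_index,
                "codon_change": f"{e.codon_before}->{e.codon_after}",
                "aa_change": f"{e.aa_before}->{e.aa_after}",
                "effect": e.effect,
                "class_change": f"{e.polarity_before}->{e.polarity_after}",
                "polarity_changed": e.polarity_changed,
            }
            for e in effects
        ]
    )
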