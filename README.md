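# quasipop

Intra-population genomic variation analysis for ultra-deep-sequenced virus
isolates.

Large dsDNA viruses such as baculoviruses are transmitted as *populations*:
one occlusion body (OB) co-occludes ~30 genomes, and a sequencing library made
from ~10¹⁰ pooled genomes at >10⁴× coverage samples that population directly.
At such depth, read counts at a position are population allele counts, and a
single alignment file supports population-genetic inference: low-frequency SNP
detection, the frequency spectrum of those SNPs, per-site selection
statistics, and the fraction of genomes carrying large deletions. `quasipop`
implements that analysis end-to-end for researchers studying viral
quasispecies structure, together with a synthetic-population simulator that
makes every estimator testable by parameter recovery.

## What it computes

- **Quality trimming + pileup** — keeps, per read, the longest run of ≥100
  consecutive bases at Phred ≥30, and builds per-position base counts split by
  strand and mate index (optionally one observation per fragment, the
  samtools mate-overlap convention).
- **SNP calling** — a non-consensus base is called when its frequency f =
  alt/depth satisfies f > 2.5×10⁻⁴ *and* it is seen on both strands and on
  both mates of a pair; records are per (position, alternate base).
- **Frequency-class clustering** — consensus k-means over the 1-D frequency
  spectrum (k = 4; 100 runs, k-means++ ×10 restarts, Hartigan-style boundary
  polish, majority-vote consensus with per-SNP and global stability). Cluster
  burdens: per-genome = Σ frequencies; per-OB = 30 × per-genome.
- **Per-site Tajima's D** — at each position with depth n, D = (π − S/a₁)/√(e₁S)
  with S ∈ {0,1} (site segregating when ≥2 bases exceed the noise floor),
  a₁ = ψ(n)+γ evaluated exactly at any depth; Welch t-test compares SNP
  subsets against the genome background.
- **Large-deletion delimitation** — pairs are re-paired after single-end
  mapping; the inner gap g = right.start − left.end is compared with its
  expectation (−42 nt for 260 bp inserts, 151 bp reads), the most-distant 5%
  (and a ≥669 nt exclusion mode that removes within-hr repeat artifacts) are
  selected, bracketed intervals are merged into calls with hr anchoring, and
  the deleted-genome fraction is estimated with a binomial interval.
- **Codon effects** — SNP → codon reconstruction on annotated ORFs (both
  strands), synonymous/missense/nonsense classification, and amino-acid
  polarity classes (AP: D,E; BP: K,R,H; NP: S,T,C,N,Q,Y; non-polar:
  G,A,V,L,I,P,F,M,W; stop → none).

## Worked example

Simulate a 20 kb circular population (four SNP classes at mean frequencies
0.27%, 9.3%, 19%, 35%; 25% of genomes carrying one hr-anchored deletion),
sequence it at 500×, and run the full analysis:

```yaml
# demo.yaml
output_dir: demo_out
seed: 7
simulate:
  enabled: true
  population:
    genome_length: 20000
    deletion_spec: {genome_fraction: 0.25, min_size: 2000, max_size: 8000, n_deletions: 1}
    seed: 7
  reads: {coverage: 500, seed: 8}
cluster: {runs: 100, seed: 7}
delscan: {min_support: 5, min_gap_exclusion: 669}
```

```bash
quasipop run-all --config demo.yaml
```

The manifest (`demo_out/manifest.json`) reports:

```
"global_stability": 1.0,
"n_deletion_calls": 1,
"n_snps": 282,
"snps_per_genome": 32.6,
"snps_per_ob": 977.8
```

282 SNPs were called (200 true loci plus low-frequency calls at the error
floor); all 100 clustering runs agreed (stability 1.0) and the four classes
came back at their generating means:

```
cluster   n     mean frequency
1        134    0.0056
2         54    0.102
3         46    0.196
4         48    0.360
```

The per-genome burden (Σ frequencies ≈ 32.6) times 30 genomes per OB gives
~978 mutations per occlusion body. The deletion scan recovered the simulated
deletion exactly — truth was `consensus:13056-17087` at carrier fraction
0.25:

```
start   end    support  boundary_uncertainty  left_anchor_hr  right_anchor_hr
13056   17087  54       8.75                  hr4             hr5
```

and the mean Tajima's D over segregating sites was −0.83, negative as
expected for a spectrum dominated by rare variants. Each stage is also
available as a subcommand (`simulate`, `pileup`, `callsnps`, `cluster`,
`tajima`, `delscan`, `effects`) operating on standard formats
(FASTA/FASTQ/SAM/VCF/GFF/BED/TSV/bedGraph).

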