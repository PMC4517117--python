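# Methods

`quasipop` analyses the genomic variation segregating *within* a single
deep-sequenced population of a large dsDNA virus (the motivating system is a
wild-type *Autographa californica* multiple nucleopolyhedrovirus isolate,
sequenced as a pool of ~10¹⁰ genomes at >10⁴-fold coverage). At such depth
every read pair derives from a different genome molecule, so read counts are
population samples: allele frequencies, site diversity and structural-variant
carrier fractions can all be estimated directly from one alignment file.

The pipeline runs: quality trimming → pileup → SNP calling → frequency-class
clustering → per-site Tajima's D → large-deletion delimitation → codon/polarity
effects. A synthetic-population module generates data with known truth so every
estimator is tested by parameter recovery.

## Synthetic populations

`PopulationSpec` describes the study conditions the analysis assumes:

- **Genome**: random sequence with a configurable A+T fraction (default 0.593,
  the baculovirus value), circular by default, default length 20 kb — a
  scaled-down stand-in for the ~134 kb genome that keeps simulations fast while
  preserving per-locus depth statistics. Homologous repeat regions (*hrs*) are
  tiles of a 70 bp unit with a 30 bp central palindrome; the default layout
  places five hrs of 280–630 bp.
- **SNPs**: four frequency classes with means 0.27%, 9.3%, 19% and 35%
  (sds 0.15%, 2%, 3%, 4%), 50 loci each by default. Class means are the
  cluster means observed in the motivating isolate; the sds are chosen so the
  classes span the ranges its per-nucleotide cluster table shows, which makes
  adjacent classes overlap at ~2σ — deliberately, since that is what the real
  frequency spectrum looks like. Variants are assigned to genomes
  *independently* (no linkage) by default, matching a library in which insert
  size (260 bp) bounds what linkage is observable; an optional block id on a
  variant makes all variants of that block co-occur, for testing the
  within-insert linkage logic.
- **Deletions**: a configurable fraction of genomes (default 25%) carry one
  multi-kb deletion whose endpoints fall inside two hr intervals
  (`anchor_mode="hr_pairs"`), emulating recombination-driven deletion between
  repeat regions; a uniform mode provides the non-anchored null. Multiple
  deletions use distinct hr pairs where possible so they remain separable
  events; carriers of different deletions are disjoint subpopulations.
- **Reads**: 151 bp paired-end reads from inserts ~N(260, 20) — mates
  therefore overlap by ~42 nt — at a per-base substitution error of 10⁻³
  (Q30). Base qualities follow a two-state model (Q34 with occasional low-Q
  tail runs), sufficient to exercise the trimming rule without modelling
  real Illumina noise. Insert-size dispersion is not reported for the
  motivating library (size-selected at 260 bp from a 100–800 bp range); the
  default sd of 20 bp is a typical gel-selection width and is configurable.

A mate whose fragment crosses a deletion junction (or the circular origin)
cannot align contiguously to the consensus; the simulator maps the larger
piece and soft-clips the remainder, which is what a local single-end aligner
does with such reads. Origin-crossing pairs are tagged (`XW`) and excluded
from downstream gap analysis. Ideal alignments are emitted as coordinate-
sorted SAM; truth as TSV/BED.

What the generator does **not** emulate: indel sequencing errors, PCR
duplicates, quality-by-cycle decay, GC-coverage bias, mapping ambiguity in
repeats. Passing recovery tests therefore shows the estimators are correct
under the stated sampling model, not that they are robust to every artefact
of real libraries.

## Quality trimming and pileup

A read is kept only if it contains a run of ≥100 consecutive bases with
Phred ≥30; the longest such run (leftmost on ties) is retained and everything
else is discarded. Retained bases are mapped through the CIGAR
(M/I/D/S supported) onto consensus coordinates and counted per base, per
strand and per mate index. Soft-clipped and CIGAR-deleted positions
contribute nothing; short-indel alleles are not tracked (large indels are
handled by the pair-distance scan, and short-indel calling is out of scope).

Counting is read-based by default, which preserves the bookkeeping invariant
that total depth equals total retained aligned length. With
`dedup_overlaps=True` (the pipeline default) the mate-overlap region of each
pair is counted once — the samtools mpileup convention — so each sequenced
fragment contributes at most one observation per position and per-locus
counts are binomial samples of the population frequency.

## SNP calling

A non-consensus base is called when its frequency (against full column
depth) strictly exceeds 2.5×10⁻⁴ and it is supported by at least one read on
each strand and at least one read of each mate index. One record is emitted
per (position, alternate base). A coarser mode thresholds the *summed*
alternate frequency at 10⁻³ instead ("all possible changes"), kept as an
alternative policy, not the default.

Note an arithmetic subtlety of these conventional thresholds: with a 10⁻³
per-base error rate, each *specific* wrong base occurs at ~3.3×10⁻⁴, which is
above 2.5×10⁻⁴ (the latter equals 10⁻³/4, i.e. treats the correct call as one
of four outcomes). The frequency floor alone therefore does not suppress
errors at very high depth; the strand and mate-pair support requirements do
the real filtering, and the false-call tests assert exactly that reduction
rather than a zero false-positive rate.

## Frequency-class clustering

SNP frequencies are partitioned into k=4 classes by consensus k-means:
100 independent 1-D k-means fits (optionally shuffling observation order
between runs — k-means is order-invariant at convergence, so this is a
robustness toggle), each run seeded by k-means++ with 10 restarts and
followed by a deterministic Hartigan-style polish of the interval cut
positions (coordinate descent on the within-cluster SSE). The polish matters:
Lloyd iteration in 1-D can stop at one of two near-tied fixed points when a
point lies close to a centroid midpoint, and without it run-to-run agreement
collapses on knife-edge data. Labels are aligned across runs by sorting
centroids ascending; each SNP's consensus label is the majority vote, its
stability the fraction of agreeing runs, and the global stability the
fraction of runs whose entire labelling matches the consensus (≥0.98 on the
study-like composition). Plain random-init Lloyd is retained as
`init="random"` but routinely splits the dominant low-frequency class and
merges the upper classes on heavily imbalanced data.

Burdens convert the table into mutation loads: the per-genome burden of a
cluster is Σ of its SNP frequencies (each frequency is the probability that
a genome carries that SNP), and the per-OB burden multiplies by the number
of genomes co-occluded in one occlusion body (default 30 ≈ ten virions ×
three nucleocapsids). Published per-genome column entries are not exactly
loci × mean frequency — the reproducible identities are the per-genome sum
(93.84 → ~94 SNPs per genome) and per-OB = 30 × per-genome (≈2815); the
bundled reference table carries the printed values so both reproduce.

## Per-site Tajima's D

At each position the reads are the sequence sample: n = column depth,
π = probability two distinct reads differ (computed from base counts),
and the site is *segregating* (S=1) when ≥2 bases exceed the noise floor
(default 2.5×10⁻⁴, the SNP threshold). Then

    D = (π − S/a₁) / √(e₁·S + e₂·S(S−1))

with Tajima's constants a₁=Σ₁ⁿ⁻¹1/i, a₂=Σ₁ⁿ⁻¹1/i², b₁=(n+1)/(3(n−1)),
b₂=2(n²+n+3)/(9n(n−1)), c₁=b₁−1/a₁, c₂=b₂−(n+2)/(a₁n)+a₂/a₁², e₁=c₁/a₁,
e₂=c₂/(a₁²+a₂). With S ≤ 1 per site the S(S−1) term vanishes. The harmonic
sums are evaluated as a₁=ψ(n)+γ and a₂=ζ(2)−ψ₁(n) (digamma/trigamma), exact
to machine precision for n up to millions of reads; direct summation is kept
as the independent test oracle. Monomorphic sites (S=0) have undefined D and
are excluded from genome summaries (a flag counts them as 0 instead);
sites with depth <4 are skipped. Because n varies with coverage, a
`subsample_n` mode downsamples every column to a common depth
(hypergeometric) to make D comparable across positions; whether per-site D
should be computed from raw read counts or from depth-normalised counts is
genuinely underdetermined, so both routes are provided.

Subsets of sites (e.g. high-frequency polarity-changing SNPs) are compared
against the rest of the genome with a Welch two-sample t-test
(Satterthwaite df, two-sided p).

## Large-deletion delimitation

Reads are treated as single-end mapped; pair identity is then reinstated and
each pair's *inner gap* (right mate start − left mate end) is compared with
the expectation (−42 nt for 260 bp inserts and 151 bp reads). The implied
deletion is inner gap − expected gap. Pairs with an unmapped or multiply
mapped mate, or spanning the circular origin, are excluded and counted.

The most-distant tail (default 5%) of the inner-gap distribution is
selected — deletions only; insertions are invisible to this method because
the insert is shorter than the summed read lengths. A second mode
additionally drops pairs with inner gap ≤669 nt (the largest hr length),
removing pairs that merely delete repeat units within a single hr; this is
the artifact-avoidance mode and the one used for deletion *calling* (in the
plain 5% mode the tail is never empty by construction, so deletion-free
libraries would still yield short positive-gap noise candidates).

Selected pairs' mate footprints form a coverage track whose peaks mark
deletion hotspots. Each selected pair with a positive inner gap proposes the
candidate interval (left mate end, right mate start); candidates with ≥50%
reciprocal overlap against a growing cluster's median interval merge, the
call boundary is the median of member endpoints (robust to stray pairs,
which the method is otherwise silent about), the uncertainty the endpoint
IQR, and calls with support below `min_support` (default 5) are dropped.
Endpoints within `anchor_slop` of an hr interval are flagged with that hr.
Deletions whose intervals overlap reciprocally by more than ~50% (e.g. two
deletions sharing both anchor hrs) merge into a single call — a limitation
shared with any bracketing-interval method at this insert size.

`deleted_fraction` estimates the carrier fraction as the proportion of pairs
implying a deletion larger than a floor, with a Clopper–Pearson 95% interval.
It is a *pair-level* estimator of the genome-level fraction and is unbiased
only over pairs whose fragment window actually brackets a junction: with
insert I and read length R, a carrier fragment shows the deletion when the
junction offset within the fragment lies in (R/2, I − R/2), so the recovery
tests restrict to pairs whose left mate starts in that window (with a margin
for insert dispersion) before comparing against the true carrier fraction.

## Codon effects and polarity classes

SNPs are mapped onto ORF annotations (GFF, 1-based closed, converted
internally to 0-based half-open); minus-strand ORFs are handled by
reverse-complementing the codon and substituting base. Both codons are
translated with the standard genetic code and classified as synonymous,
missense or nonsense; overlapping ORFs yield one effect each, none
privileged. Amino acids are grouped by charge and polarity: acidic-polar
(D, E), basic-polar (K, R, H), neutral-polar (S, T, C, N, Q, Y) and
non-polar (G, A, V, L, I, P, F, M, W); stop codons have no class, and a
nonsense change therefore counts as polarity-changing. This class membership
was inferred from the full set of 60 published codon changes bundled as
reference data (every row reproduces exactly); W, F and V do not occur in
that set and follow the standard scheme. TSS proximity is the minimum
absolute distance to a provided TSS list, reported with the gene label.

## Numerical and testing choices

- Coordinates are 0-based half-open everywhere internally; 1-based closed
  only in human-readable formats (GFF, VCF).
- All randomness flows through `numpy.random.default_rng` seeds recorded in
  the output manifest; identical config + seed reproduces byte-identical
  artifacts.
- Tie-breaks are deterministic throughout: leftmost quality run, stable
  input-order ranking at the tail cut, first-mate-wins overlap dedup,
  leftmost k-means boundary improvement.
- Recovery tests run on a 20 kb population at 1000× (the package's
  study-scale condition) plus smaller 5–10 kb populations at 100–500× for
  unit-level checks. Statistical assertions are sized for their sample
  counts: with ~200 loci, "99% of loci inside 99% intervals" is asserted as
  a binomial calibration test (observed misses ≤ the 99th percentile of
  Binom(n, 0.01)) rather than a point bound, which would reject a perfectly
  calibrated estimator about half the time at this n.
- Class-recovery assertions tolerate draws whose true frequency falls in the
  overlap between adjacent generating classes (irreducible Bayes error of
  the mixture); disagreements must stay between neighbouring classes.

## Known limitations

- No short-indel calling, base-quality recalibration, or consensus
  re-estimation; annotations are inputs, never computed.
- The deletion scan cannot see insertions, separates overlapping deletions
  poorly, and excludes origin-spanning pairs rather than unwrapping them.
- Genome-wide selection summaries from real isolates (e.g. a mean D near
  −0.55) depend on the deposited read set and are not reproduced by the
  synthetic tests, which validate the estimators, not the biology.
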