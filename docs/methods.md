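# Methods

`orgmut` analyses two complementary kinds of mutation in plant organellar
(mitochondrial and plastid) genomes: **point mutations** measured by duplex
consensus sequencing, and **repeat-mediated structural variation** measured
by split alignments of long reads.  This note describes the models the
package implements, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical conventions chosen where
the underlying protocols leave them open.

## Reference model

Organellar genomes are treated as single circular sequences with 1-based
inclusive coordinates.  A repeat catalog row prints each copy as
`start–end`; a copy printed with descending coordinates is on the opposite
strand (an inverted pair) and is stored internally as an ascending interval
plus an orientation flag.  Printed repeat lengths are alignment lengths:
when the two copies of a pair differ by an indel, the printed length matches
one copy's span but not the other's, and the catalog reader accepts either.

Gene features partition the genome into intergenic, CDS, intronic, rRNA, and
tRNA site classes.  Overlaps are resolved with the precedence
tRNA > rRNA > CDS > intron: the structural RNA genes are short, and burying
them inside CDS annotations would distort frequencies computed over the
small rRNA/tRNA denominators.  Sites covered by equal-precedence features on
*both* strands are excluded from strand-asymmetry denominators, because
template/non-template orientation is undefined there.  These overlap rules
are this package's choices; the upstream analyses do not document theirs.

Trinucleotide contexts are read with circular wraparound, always on the
strand carrying the pyrimidine of the mutated site, so that complementary
substitutions (C>T on the plus strand, G>A on the plus strand) collapse onto
one class with one context.  Contexts touching an `N` are unusable and
excluded from both numerators and denominators.

## Duplex consensus calling

Duplex sequencing tags both strands of each source molecule; reads therefore
group into two strand-families per molecule.  The caller:

1. groups reads by tag (families whose reads map more than a slop apart are
   split by locus; untagged reads are rejected and counted);
2. builds a per-strand consensus — a base is called when at least
   `strand_consensus_threshold` (default 0.9) of that strand's reads agree,
   otherwise the position is `N`;
3. accepts a duplex base only where both strand consensuses agree and
   neither is `N`; families with fewer than `min_reads_per_strand`
   (default 3) reads on either strand are rejected (a counted outcome);
4. calls mismatches as SNVs, 1-bp length differences as left-aligned
   (VCF-convention) insertions/deletions, and merges two adjacent SNVs on
   one molecule into a single dinucleotide call;
5. marks calls within `end_trim` (default 10) bases of a molecule end;
6. filters NUMT/NUPT artifacts: the variant's local haplotype — `k_flank`
   (default 20) bases each side with the molecule's duplex-confirmed
   variants applied, including the alternate allele — is searched against
   the nuclear genome and its reverse complement; a hit within
   `numt_max_mismatch` edits (default 0, the strictest reading of
   "comparing putative mutations directly against the nuclear genome")
   marks the call `numt`.  Windows truncated by a molecule end scale the
   edit allowance proportionally.

The consensus thresholds and end trim are conventional duplex-pipeline
values; the upstream protocol defers to its own prior pipeline without
printing them, so all are configuration-exposed and tagged
`artifact-default` in run manifests.

A structural invariant of the design: a sequencing error present on only one
strand-family can never produce a pass call — at best it turns the position
into an `N`.  This is asserted both as a unit test and statistically on
10^8 synthetic duplex bases.

**Frequencies.**  Every frequency is `count / duplex coverage of the sites
where that count could have occurred`.  Coverage counts pass-filter
consensus molecules only, with `end_trim` bases removed from each molecule
end so numerator and denominator cover exactly the same bases.  Dinucleotide
calls are excluded from the SNV numerator by default (they are reported
separately); a flag reverses this.  Region, strand, and trinucleotide
denominators are masked sums over the per-position depth vector, since a
position's region/strand/context is a property of the reference; this makes
the partition identities (Σ context coverage of the pyrimidine classes =
total coverage) exact by construction.

**Strand asymmetry.**  "Template strand" means the strand RNA polymerase
reads; a gene's annotated strand carries the sense (non-template) sequence.
A collapsed C>T call whose pyrimidine lies on the gene's sense strand reads
as C>T on the non-template strand; otherwise it reads as G>A there.  The
per-region frequencies normalize each reading by the non-template-strand
coverage of its source base (C for the pyrimidine reading, G for the purine
reading).  Complementary readings are compared with a paired Wilcoxon
signed-rank test or a paired t-test across replicates.  Zero-frequency cells
are left as zeros; no pseudocounts are added before any test, and
log-transformation is left to plotting.

**Fold enrichments** pool numerators and denominators across cells and
replicates before dividing (the ratio of pooled frequencies).  The mean of
per-replicate ratios is not used: it is undefined for empty cells and biased
for small counts.

No multiple-testing correction is applied by default (raw p-values are
reported); a Benjamini–Hochberg helper is available.

## Long-read structural analysis

Reads are classified purely by split-alignment geometry:

| hits | geometry | class |
|---|---|---|
| 0 | — | `unmapped` |
| 1 | covers read within `max_unexplained` | `single_hit_clean` |
| 1 | large unexplained remainder | `single_hit_indel` |
| 2 | opposite orientations | `two_hit_inverted` |
| 2 | same orientation, genome order follows read order, genomic gap | `two_hit_direct_deletion` |
| 2 | same orientation, genome order reversed | `two_hit_direct_circular` |
| ≥3 | — | `multi_hit_excluded` (not reconstructed) |

`max_unexplained` defaults to 50 bp + 5% of read length; the junction gap
slop is 50 bp; hits shorter than `min_hit_len` (100 bp) are dropped first.
Because the two hits flanking a recombination junction both extend through
the (near-)identical repeat sequence, their read intervals overlap by up to
the repeat length; the classifier splits the shared interval at its midpoint
before reading junction coordinates, which leaves each junction inside its
repeat copy.  A hit whose read interval is ≥95% contained in a longer hit is
a repeat-copy shadow alignment and is discarded; a genuine ≥95% mutual
overlap is ambiguous and classified by the longer hit alone, with a warning.

Deletion lengths are junction differences: for junction coordinates
`a < b`, the reported length is `b − a` (calibrated against the printed
106-bp deletion at plastid positions 148490–148596).

Breakpoints match a repeat pair when each junction end lies within one
copy's interval extended by `tolerance` (default 100 bp), one junction per
copy, with geometry consistent with repeat orientation (inverted geometry ⇔
inverted pair).  Ties between equally distant repeats are ambiguous and
unassigned.

A read **spans** a repeat pair when one hit fully covers either copy plus
`flank` (default 100 bp) on both sides, or when it is a recombined read
matched to that pair; both copies pool, each read counts once.  Per-repeat
recombination frequency is recombined/spanning.  Genome-wide frequencies
include only repeats whose recombining-read totals summed across replicates
reach a threshold (10 for mtDNA, 3 for cpDNA — the plastid genome recombines
far less) and pool counts over the included repeats, per replicate.

Indel calls require at least 2 reads supporting the *exact same* (position,
length) after left-normalization — long-read indel artifacts are rampant,
and near-identical candidates deliberately do not pool.

Coverage profiles average depth in 1,000-bp tiling windows; the mutant:WT
ratio vector is rescaled to mean exactly 1 over finite windows, and windows
with zero WT depth are flagged and excluded from the rescaling.

**Hit providers.**  Hits may come from BLAST outfmt-6 tables or SAM files
with supplementary alignments (minimap2- or BLAST-style workflows), or from
the built-in seed-and-chain aligner: exact 13-mers at stride 5 are chained
by diagonal continuity (band 120 bp, gap ≤ 400 bp, ≥4 seeds, ≥100 bp).  At
5% per-base error an exact 13-mer survives with probability ≈0.51, so clean
seeds land every few bases and chains essentially never fragment; the
chainer is exact enough for all synthetic tests and keeps the suite free of
subprocess dependencies.

## Synthetic data

The generators exist to give every pipeline stage a measurable truth.

*Genomes* are uniform-random sequence with non-overlapping planted genes and
repeat pairs; the second repeat copy differs from the first at exactly
`round((1 − identity/100) × length)` positions.  Repeat positions can be
pinned explicitly — the recombination-recovery tests place each pair in its
own 22-kb territory so that the recombination products of one pair cannot
reach another pair's copies and contaminate its spanning denominator.

*Duplex families* are simulated in the same sparse representation the caller
consumes: a molecule is an interval plus planted differences; planted
mutations appear on all reads of both strand-families, and sequencing errors
are i.i.d. per read.  Substitution rates are pyrimidine-keyed per-site
probabilities, modified by per-(class, 5′, 3′) context multipliers and by a
template-strand factor *b* that multiplies the rate at genic sites whose
pyrimidine lies on the template strand (*b* = 1 ⇒ symmetric).  Default rates
sit in the wild-type organellar regime (order 10⁻⁷ per molecule-base,
transition-dominated).  One planted event per molecule-site: collisions
between substitution, indel, and dinucleotide plantings are redrawn.  Duplex
tags are unique strings; family size is a fixed reads-per-strand (no tag
collisions, no family-size distribution).

*Long reads* have lognormal lengths (median ≈2.5 kb, matching typical
organellar nanopore libraries) truncated at 200 bp.  Every repeat whose copy
a molecule spans (copy + 100-bp margin) receives one Bernoulli(f) trial in
genomic order; the first success sets the geometry: inverted pairs switch
strand at a crossover uniform within the repeat; direct pairs yield
deletion-type or circular-type products in a configurable mix (default 1:1 —
the real mixture is not documented anywhere and is a free parameter).
Circular-type reads are emitted spanning the circle junction with the same
100-bp margin beyond both edges of the hybrid repeat copy, because a
junction inside the repeat or closer to a read end is seamless sequence that
no aligner could detect; molecules too short for that fall back to the
deletion-type product.  The nanopore error model is i.i.d. substitution
(50%) / insertion (25%) / deletion (25%) with no homopolymer bias — adequate
because classification depends on alignment geometry, not base accuracy.
Reads are drawn with linear (non-origin-crossing) starts and the classifier
treats the genome linearly.

*NUMT fixtures* embed a diverged copy of an organellar interval in random
"nuclear" sequence; contaminating families are drawn from the copy so they
carry all overlapping paralog alleles.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: PCR duplication and amplification bias, quality-score
structure, homopolymer-dependent error, tag collisions, chimeric library
artifacts, heteroplasmy dynamics, and real NUMT/NUPT landscapes (one planted
paralog per fixture).  Recovery results certify the *bookkeeping and
estimators*, not robustness to every artifact of real libraries.

## Statistical checks and problem sizes

The acceptance suite runs the whole pipeline at these scales (chosen to keep
estimates well-powered at desk scale):

- recombination recovery: five 300-bp repeats at f ∈ {0, 0.1, 0.3, 0.7, 1}
  on a 120-kb genome, 16,000 reads per mode (error-free and 5%), giving
  ≥500 spanning reads per repeat; every estimate must fall inside its 99%
  binomial confidence interval, with f = 0 and f = 1 recovered exactly;
- point mutations: 1 × 10⁻⁶ per molecule-base planted over 334,000
  300-bp molecules (≥10⁸ duplex bases) with 10⁻³ per-read error; the
  recovered frequency must lie within 3 Poisson standard errors and no
  single-strand error may surface as a pass call;
- context multiplier 8.4 (5′-pyrimidine contexts of C>T) and template bias
  b = 5 recovered within 95% confidence intervals on ≥2,000 planted events;
- type-I error of the paired strand-asymmetry tests measured over 100 null
  cohorts of 6 replicates each; the paired t-test holds its nominal 5% size.
  With the typical 3 biological replicates the Wilcoxon signed-rank cannot
  reject at α = 0.05 at all (its smallest attainable p is 0.25), so the
  simulation uses 6 replicate pairs, where the Wilcoxon's attainable level
  is 1/32 — the test is then nominally sized given its discreteness.

## Known limitations

- Reads with ≥3 local hits are excluded, not reconstructed; at high
  recombination activity this underestimates genome-wide frequencies.
- The chainer reports approximate hit endpoints (seed-boundary resolution,
  a few bases error-free, tens of bases at 5% error); junction matching
  absorbs this through its 100-bp tolerance, but base-resolution breakpoint
  calling would need a local realignment step.
- Circular/tandem products are distinguished from deletions only by the
  order of the two hits; a read sampling a circle without crossing its
  junction is indistinguishable from an ordinary read.
- The duplex caller consumes aligned, tagged reads; mapping itself is out of
  scope (any tagged-SAM-producing aligner can feed it; the synthetic path
  needs none).
- Group comparisons are thin wrappers over scipy routines; with 3 replicates
  per group their power is very limited, exactly as in the motivating
  experimental design.
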