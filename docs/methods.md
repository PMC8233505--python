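# Methods

This note records the models, estimators and design choices behind `cnsvar`,
in the order a reader would meet them: the variation model, the caller, the
statistics, the synthetic data that everything is tested against, and the
numerical conventions.

## The variation model

The unit of analysis is a reference-annotated conserved noncoding sequence
(CNS): an interval of at least 15 bp with its nucleotide sequence and an
associated gene (its proximate gene — the nearest gene by boundary
distance). For each accession assembly every reference CNS receives exactly
one of three statuses:

- **collinear** — a qualifying match exists whose proximate gene in the
  accession maps, through the ortholog table, back to the element's
  associated reference gene;
- **PosV** (positionally variable) — qualifying matches exist but none in
  the syntenic gene context; the element is present at a different locus;
- **PAV** (presence–absence variable) — no qualifying match anywhere.

Collinearity takes priority over positional variation: if an element is
found both at its syntenic site and elsewhere, it is collinear and the
other occurrences are recorded as secondary matches. Synteny is decided by
proximate-gene orthology alone, not by element order or by which side of
the gene the match falls on; an element that switches from upstream to
downstream of the same gene remains collinear. On a chromosome with no
annotated genes a match cannot be syntenic and counts toward PosV.

## The caller

Search is seed-and-extend. A sorted index of all exact 11-mers of the
accession assembly (2-bit packed, forward strand) is probed with the
element's 11-mers on both strands; each hit nominates a candidate diagonal,
diagonals closer than the element length are merged into one candidate (a
cluster's alignment window spans all its member diagonals — elements with
internal repeats spread their seeds), candidates are ranked by seed support
and capped (default 50). Each candidate window is aligned semi-globally
(free end gaps on the window, the whole element consumed) with edlib;
identity is `1 − edits/element_length`, coverage is the aligned window span
over the element length, capped at 1. Matches require identity ≥ 0.90 and
coverage ≥ 0.90 by default. The unit tests hold the reported identity
against an independent dynamic-programming alignment oracle.

Seed length 11 < 15 guarantees a seed for every verbatim occurrence of even
the shortest element. The 0.90 identity default tolerates intraspecific SNP
divergence (~0.5%/bp: a 150 bp element with binomial(150, 0.005) mismatches
essentially never falls below 0.93) while keeping chance qualifying hits
rare; both thresholds are exposed in `CallerParams`. Note a hard limit at
this scale: a 15 bp element has, by chance alone, on the order of one
0.87–0.93-identity near-match per few megabases, so presence thresholds
below ~0.9 are not meaningful for the shortest elements.

The per-base conservation-score gate (`phastcons_filter`) reproduces the
element definition used for the reference CNS catalogue: a run of at least
seven consecutive positions scoring above 0.82, and no run longer than
twelve consecutive positions below 0.55.

## Statistics

**Independence expectation.** Accession *i* varies in `k_i` elements drawn
uniformly without replacement from the universe of `N`; accessions are
independent. The expected number of distinct variable elements is
`N(1 − Π_i(1 − k_i/N))`, exact under this model (checked against a
Monte-Carlo oracle). Observed counts far below this expectation indicate
recurrent variation of the same elements; the shared-event fraction
(columns with ≥2 hits over columns with ≥1) quantifies the same thing
directly.

**Set overlap.** Overlap of two element sets in a universe is tested with
the exact hypergeometric tail, computed by direct pmf summation over the
support — no normal approximation. The default tail is the survival
convention P[X > x]; the inclusive tail P[X ≥ x] is available and every
result records which was used. Worth knowing: at study-like magnitudes
(universe ≈ 63k, sets ≈ 1.5k/4.8k, overlap ≈ 118) the two conventions
differ by ~0.04, so the convention must always be reported.

**k-mer expectation.** Under a uniform base model a fixed k-mer is expected
`(L − k + 1)/4^k` times on one strand of an L-bp genome; a flag doubles it
for both strands. This is the motivation for a 15 bp length floor: ~33,000
chance hits for a 6-mer in 135 Mb versus ~0.13 for a 15-mer.

**Rarefaction** subsamples accessions without replacement; the mean at full
depth equals the observed distinct count exactly. **Binary PCA** centers
but does not scale the indicator matrix (the columns share a scale);
variance percentages derive from squared singular values. The
**structure regression** is ordinary least squares of a CNS-variation axis
on supplied neutral axes (e.g. three whole-genome SNP PCA coordinates),
reporting R² with and without one covariate; under the null its mean R² is
p/(n−1), which the tests verify.

**Permutation nulls.** Interval permutation preserves lengths and draws
each start uniformly over all valid (chromosome, start) pairs, so
chromosome assignment is proportional to chromosome length; replicate r is
a deterministic function of (seed, r). The gene-distance test uses the
two-sample Kolmogorov–Smirnov statistic of observed absolute distances
against the pooled permuted distances, with the empirical p-value
`(1 + #{D_perm ≥ D_obs})/(n_perm + 1)`; each replicate is scored against
the pool of the *other* replicates (leave-one-out) so the reference
distribution is exchangeable with the observed set — the test suite checks
type-I error ≤ 1.5× nominal at α = 0.05 over 200 null worlds. Repeat
proximity uses the same machinery with the median nearest-repeat distance
as the statistic. Permuted intervals may overlap genes and each other (no
exclusion by default); distance permutation restricts placement to
chromosomes carrying at least one gene, since gene distance is undefined
elsewhere.

**Chromatin enrichment.** Peaks are merged before counting; an interval
overlaps if it shares ≥1 bp (half-open coordinates, so touching intervals
do not overlap). Fold enrichment is the observed overlap count over the
mean permuted count. The length-matched control subsamples a reference
class to the query's length histogram in 5-bp bins without replacement —
the binned histogram is preserved exactly — addressing the concern that a
shorter class overlaps less for purely geometric reasons.

**Expression association.** Per accession, a gene's accession-side CNS
count is its retained collinear elements plus PosV elements whose new
proximate gene maps back to it; gain/loss/no-change follows the sign of the
change. PosV elements are counted at their new gene and removed from the
old one. The universe is genes with orthologs in that accession (expression
comparison is only defined for shared genes). Each (category, direction)
cell gets exact hypergeometric over- and under-representation tails
(inclusive; they share the boundary mass, so p_over + p_under ≥ 1).

**Selection.** Nei–Gojobori (1986) unweighted counting: a codon's
synonymous site count is the fraction of its nine single-nucleotide mutants
preserving the amino acid (changes to stops count as nonsynonymous; S + N =
3 per codon); codon differences average over all minimal mutational
pathways with equal weight, excluding pathways through stop codons unless
every pathway is blocked. Per pair, differences are summed over codons and
divided by pair-averaged site totals; π_N and π_S are the means of the
per-pair proportions, as raw p-distances without multiple-hit correction —
appropriate at intraspecific divergence (~1–3%), where the Jukes–Cantor
correction would shift values by under 2% of their magnitude. π uses
pairwise deletion of gapped/ambiguous sites. Group analyses can require a
minimum number of accessions per gain/loss/no-change class (default 2).

## The synthetic data

The generator is first-class, tested code; its defaults are the desk-scale
study conditions used throughout the test suite: a 2 × 1 Mb reference, 500
genes (1 kb), 2,000 CNS of 15–150 bp placed in intergenic space near genes
(geometric boundary gap, mean 300 bp), 200 repeats, and 5 accessions each
carrying 50 planted PAV deletions and 100 planted PosV relocations over
background SNPs at 0.005/bp and 1–3 bp indels at 5·10⁻⁴/bp. These
per-accession event counts are deliberately a few-fold above the real-data
per-accession averages (~0.26% PAV, ~1.4% PosV of the universe) so that
recovery statistics have usable counts at a 2,000-element universe; rates
and counts are all configurable. Background mutations never touch CNS
bodies, so recovery tests isolate the caller's thresholds; a separate
`cns_snp_rate` (default 0) mutates surviving element copies to stress the
identity threshold. A PosV insertion keeps its strand with probability 0.5.
The ortholog table is an identity mapping with renamed accession gene ids —
gene gain/loss is outside the caller's scope.

Three generator-level guarantees keep the truth table semantically correct,
rather than tuning the caller:

1. **Uniqueness screening.** Each planted element is screened for a second
   occurrence at ≥ the caller's acceptance identity elsewhere in the
   reference; colliding loci are rewritten with fresh random bases. Without
   this, a "deleted" 15–16 bp element can legitimately be found at a chance
   near-duplicate, making the planted PAV label wrong (expected a handful
   of such collisions per 2 Mb). Screening below the acceptance threshold
   is infeasible for the shortest elements (see the caller section).
2. **Proximate-gene margins.** Elements and landing sites are only placed
   where the nearest gene beats the runner-up by ≥100 bp, so small indel
   drift cannot flip the gene assignment.
3. **Geometry validation.** Excising a 150 bp neighbour can still shift
   distances enough to flip an assignment, so after building each accession
   the generator recomputes every surviving element's proximate gene in
   final coordinates and resamples the accession draw on any flip.

A PosV landing is an insertion at a reference point (it consumes no
reference space); distances to its anchoring repeat are therefore measured
from that point, and the corridor between landing and repeat is reserved so
no later insertion stretches the planted proximity. Peak tracks cover an
exact rounded fraction of collinear and PosV elements (covering peaks are
clipped away from all other elements; background peaks avoid elements
entirely), so planted coverage fractions are exact by construction.
Expression labels give gain-genes `de_odds_gain_up` times the baseline odds
(default baseline rate 0.10) of being upregulated, and likewise for
loss/down. Codon alignments mutate each ancestral codon synonymously or
nonsynonymously with per-codon probabilities proportional to its NG site
counts, calibrated so realized pairwise diversity converges to the targets;
double-hit collisions bias this by under 2% at the default rates, well
inside the Monte-Carlo band the tests use.

What the generator does *not* emulate: real TE families or sequence
homology of repeats, recombination, gene gain/loss, assembly and annotation
error, read-level artefacts, and genome-scale base composition structure.
Passing tests therefore demonstrate correctness of the algorithms under the
stated variation model — not robustness to assembly quality or annotation
noise in real pangenome data.

## Numerical conventions and edge cases

Coordinates are 0-based half-open internally; GFF3 is written 1-based
inclusive, BED 0-based half-open. Signed gene distances are 0 on overlap,
negative 5′ of the gene start in genomic coordinates, positive 3′ of the
gene end; equidistant genes tie-break to the smaller gene start. All
randomness flows from explicit seeds through `numpy.random.Generator`
streams keyed by stage, so reruns are byte-identical at the file level.
Degenerate inputs raise rather than guess: empty score windows, zero
variable elements, zero-variance count vectors, constant indicator
matrices, rank-deficient designs, single-sequence alignments, infeasible
packing or unreachable diversity targets. Chromosomes without repeats
produce infinite distance sentinels that are excluded from medians with a
warning; π_N/π_S with zero synonymous diversity reports a missing ratio.

Problem sizes in the test suite (120 kb worlds for unit tests, the 2 × 1 Mb
five-accession world for recovery, 10³ permutations for enrichment, 200
simulations for calibration, 10⁴ codons for diversity recovery) were chosen
as the smallest scales at which the statistical assertions have comfortable
margins.
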