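# Methods

This note documents the models, the numerical choices, and what the
synthetic generators do and do not emulate.

## Disease model and liability classes

`DiseaseModel` is a single-locus autosomal-dominant model: disease allele
frequency *p* (default 10⁻⁴ — a variant absent from population databases and
from 180 local controls), penetrance vector (f₀, f₁, f₂) = P(affected | 0/1/2
disease alleles) defaulting to (0, 1, 1), and one age-based liability class:
members younger than the onset threshold (default 25 years) are *pre-onset*.
The default pre-onset policy treats them as phenotype-unknown — a young
unaffected carrier is simply uninformative — because any specific reduced
penetrance value for the pre-onset class would be a guess; a
`("reduced_penetrance", v)` policy is available and multiplies the penetrance
vector by *v* for pre-onset members.  Individuals with no recorded age are
assigned to the post-onset class.

Affected individuals who married into the family are handled by an explicit
exclusion set rather than a phenocopy rate: their phenotype is masked
(genotypes still contribute) wherever linkage or cosegregation is computed.
This mirrors treating them as founding parents whose disease has an
independent cause.

## Two-point pedigree likelihood

The marker and disease loci are both biallelic.  Each individual's latent
state is a phased two-locus genotype: an ordered (paternal, maternal) pair
of haplotypes, each haplotype one of {d·a, d·A, D·a, D·A} — 16 states.
Founder states get Hardy–Weinberg haplotype priors under linkage
equilibrium.  A parent transmits each intact haplotype with probability
(1−θ)/2 and each recombinant with θ/2.  Phenotypes multiply in penetrance
terms; a typed marker genotype restricts states to the matching
alternate-allele count.  Missing genotype calls and unknown phenotypes
simply contribute no constraint.

Two engines evaluate the same factor product:

- **peel** (default): variable elimination with a greedy min-degree
  elimination order over the factor graph.  On loop-free pedigrees this is
  the classical anterior/posterior peeling recursion; the min-degree order
  keeps intermediate tables near the pedigree's treewidth (a naive
  generation-by-generation order can join every married-in spouse factor at
  once).  Tables are renormalized after each elimination and the scale
  accumulated in log₁₀, so deep-pedigree likelihoods far below double range
  stay exact.
- **enumerate**: depth-first summation over per-individual states with
  zero-weight pruning.  Exponential, intended for small or heavily
  constrained pedigrees, and used throughout the tests as the independent
  oracle (agreement is asserted to 10⁻⁹ log₁₀ units on randomized
  pedigrees of up to 12 members).

Monozygotic-twin groups (PED column 8) share a single genotype variable:
one pair of meioses, with both twins' phenotype and genotype weights
multiplied onto it.  Unflagged twins are dizygotic, i.e. ordinary siblings.
Pedigrees with marriage loops are handled to the extent the elimination
order keeps tables tractable; heavily inbred loop structures are out of
scope.

LOD(θ) = log₁₀L(θ) − log₁₀L(½), reported on the grid
{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5} by default; the value at θ = ½ is 0
by construction, and a configuration impossible at θ = 0 (an obligate
recombinant under full penetrance) reports −∞ there.  The marker allele
frequency defaults to 10⁻⁴, appropriate for scoring the candidate variant
itself as the marker.

## ELOD

ELOD is used as a family-informativeness score: the LOD a family would be
expected to yield if the causal locus were typed with a fully linked,
fully informative marker.  It is computed as **E[LOD(θ=0) | observed
phenotypes]**: disease-locus genotypes are drawn from their exact posterior
given the phenotypes (single-locus peeling followed by backward sampling
through the recorded elimination factors), the marker of each realization is
set equal to the disease genotype restricted to the typed members, and the
resulting LOD(0) values are averaged (Monte-Carlo standard error reported).
An exact mode enumerates all genotype configurations with nonzero posterior
weight instead — cheap under full penetrance, where the phenotypes pin most
genotypes, and on small pedigrees generally.

Conditioning on phenotypes is deliberate: the expectation under
*unconditional* gene dropping of a 10⁻⁴ allele is essentially zero for any
family (almost no replicate carries the allele), which would make the score
useless for family selection.  Conditionally, a fully informative
phase-known family with *n* informative meioses yields exactly n·log₁₀2 in
every realization, the textbook value.

## Consequence annotation

Transcript models carry exons, CDS intervals and the spliced coding
sequence; all mapping happens in transcript orientation, so minus-strand
models reverse-complement alleles and mirror intron offsets, and a
minus-strand transcript produces byte-identical HGVS strings to its
plus-strand mirror (property-tested).  Coding SNVs translate the affected
codon with the standard genetic code (codon index ⌈c/3⌉); intronic positions
within 8 nt of an exon junction are `splice_region` — wide enough that a
donor+4 variant is classified splice-relevant — and named with donor `+N` /
acceptor `−N` offsets from the nearer junction (ties go to the donor side).
Indel protein names are simplified (`fs`/`del`/`ins` without downstream
termination prediction), and multi-nucleotide substitutions are not
supported.  A reference-allele mismatch between variant and transcript is an
error, not a silent re-interpretation.

## Filter cascade

Stage order: region (keep exonic + splice_region) → dominant sharing → rare
functional consequence.  "Absent in unaffected members" is read
conservatively as an *observed* homozygous-reference call: a missing call in
any sequenced member drops the record.  Sharing requires call exactly 1 in
every sequenced affected (heterozygous sharing; a homozygous-alternate
affected drops the record).  The rarity rule keeps af < 0.01 **or no
frequency entry** (novel variants are encoded by an absent `AF_POP` key, not
by 0).  The kept-consequence set is {missense, stop gain, stop loss, stop
retained, frameshift, inframe indel, splice region}; stop-retained is
included because the study's own retained-candidate table contains one.
Candidates sort by damaging-verdict count (descending), novel before known,
then gene name.

The consensus ranking counts verdicts in the vocabulary {pathogenic,
damaging, probably damaging, possibly damaging, disease causing,
deleterious} (case-insensitive); unrecognized verdict strings warn and count
as non-damaging.  The six external predictors themselves are not
re-implemented.

## Antibody-array analysis

%CFC = 100·(treatment − control)/control on globally normalized intensities,
always recomputed from intensities rather than trusted from input.  Global
normalization scales each sample so its total spot intensity equals the
across-sample mean total (the vendor's exact procedure is unpublished; this
choice preserves within-sample ratios and is idempotent).  The duplicate
%error range is the half-range over the mean, 100·(max−min)/(2·mean) — also
a documented stand-in for an unpublished vendor formula; when error
percentages arrive in the input they are consumed as given.  The hit rule
applies |%CFC| ≥ 60 (magnitude, so suppressed targets count), error sum
< 0.85·|%CFC|, and max intensity ≥ 1,000 — note the intensity floor is in
absolute normalized units, while the other two criteria are scale-free.
Rows that fail a stated criterion are flagged with the failing criterion
named, never silently included, and rows whose printed %CFC disagrees with
their printed intensities by more than ±0.01 are flagged as internally
inconsistent (the packaged table contains exactly one such row).

## Synthetic generators

All generators are deterministic given their spec's seed (same spec + seed ⇒
byte-identical output).

**Family cohorts** emulate the study family's shape: a founder couple,
married-in spouses, sibships of 2–5, three generations by default, ages
stratified ~27 years apart with the youngest generation straddling the
25-year onset threshold.  The planted variant enters as a single
heterozygous founder allele and is gene-dropped; affection is a Bernoulli
draw from the penetrance implied by carrier status and liability class.
Background variants are phenotype-independent: per-sample Hardy–Weinberg
draws at frequencies from Beta(0.8, 0.8) truncated to [0.001, 0.5] (chosen
to produce both common and borderline-rare variants around the 0.01
threshold), with 2% novel (no `AF_POP` key).  The default table size is
20,000 variants — an exome at reduced scale; tests and the acceptance script
use 1,000-variant tables so that hundreds of cohorts fit comfortably in a
run, which loses nothing since recall is structural, not size-dependent.
What the generator does *not* emulate: linkage disequilibrium between
background variants, sequencing error, genotype-calling artifacts, or
read-level data.  Passing recovery tests therefore demonstrate the logic of
the cascade, not robustness to call errors.

**Array datasets** plant `n_true_hits` (default 20) among 878 spots (613
phosphosite + 265 pan-specific antibodies) with |log₂FC| drawn from
[1.2, 3.0] and random sign, lognormal baselines (median 5,000, σ=0.8 —
a realistic mid-range chemiluminescence scale under which only a small tail
of spots sits below the 1,000-intensity floor), and multiplicative duplicate
noise at CV 5%.  Non-hit spots have ratio exactly 1 before noise, so false
positives are essentially impossible at the 60% threshold; recall is limited
only by dim spots failing the intensity floor.

**MSAs** draw unconserved columns uniformly over the 20 residues per
sequence and force conserved columns to a single residue — a null model for
conservation scoring, not a phylogenetic simulator.

## Known limitations

- Two-point parametric linkage only: no multipoint, no non-parametric
  allele-sharing statistics, no X-linked models.
- The enumeration engine and the exact ELOD mode are exponential; they are
  guarded for small or penetrance-constrained problems.
- Annotation handles one transcript per gene and synthetic coordinates; it
  is not a genome-build-aware annotator.
- The packaged family fixture is a *reconstruction*: published counts
  constrain it, but per-individual structure and genotypes are invented, so
  its LOD/ELOD values are anchors of the right magnitude rather than exact
  reproductions of the published 2.36/0.29/2.66 (whose model parameters and
  software were never stated).  The deceased obligate-carrier founder is
  coded phenotype-unknown: under full penetrance an unaffected carrier would
  have zero likelihood.
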