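# Methods

## The analysis

`poolskim` implements a pooled genome-skimming SNP pipeline for high-copy
loci — a chloroplast genome (cpDNA, maternally inherited, non-recombining,
single haplotype per individual) and a nuclear ribosomal repeat (nrDNA,
multi-copy, internally heterogeneous).  Each sampling site contributes one
pooled library of `pool_size` individuals (default 8); the pipeline never
sees individual genotypes, only per-position read counts.

The analysis proceeds in four stages.

**1. Pool calling.**  For each site-locus pileup (per-position, per-strand
base counts), a position is masked to `N` when total depth falls below
`min_coverage` (default 20×).  Otherwise the consensus is the plurality
base, and any non-consensus base is reported as a *within-pool variant*
when its frequency reaches `min_variant_frequency` — default 1/pool_size =
12.5%, the smallest contribution one pooled individual can make — and is
supported by at least one read on each strand (`require_both_strands`,
default on; a one-strand-only signal is treated as a sequencing artefact).
The frequency denominator is total depth at the position (all bases, both
strands): the plain reading of "variant frequency", so a third allele's
reads dilute the others.  Consensus ties at exactly 50/50 resolve to the
reference base when one is supplied and is among the tied maxima,
otherwise to the alphabetically first base; the losing tied allele is
still eligible as a (50%) variant.  Ties are vanishingly rare at realistic
depth, but the rule makes the caller deterministic.

**2. SNP cataloguing.**  Site consensuses of one locus share reference
coordinates, so the "alignment" is positional stacking; no realignment is
performed (external data must arrive pre-aligned and equal-length).
Columns masked in *any* site are excluded from analysis everywhere —
masking propagates, mirroring the removal of low-coverage areas before
annotation.  Each analysable polymorphic column becomes one record:

* `fixed_difference` — consensuses differ between sites and no pool is
  internally polymorphic there;
* `within_pool_only` — consensuses agree, but some pool is internally
  polymorphic;
* `mixed` — both at once.  Mixed columns are excluded from
  fixed-difference counting (the conservative reading of how the two SNP
  classes interact).

Privacy is attributed on minority-allele carriers: a SNP is *private* to a
site, catchment or region when every site carrying a non-majority allele
lies inside that group and at least one scored site lies outside it.  The
site-count majority breaks ties to the alphabetically first base.
Within-catchment diversity is the count of fixed SNPs private to the
catchment ("unique fixed SNPs"); between-group differentiation counts
analysable columns where group A is fixed for one base and group B for a
different one, with no within-pool variant in any member pool.

**3. Diversity summary.**  Per-bp SNP rates divide by the **full**
assembled locus length (defaults 124,678 bp cpDNA, 5,813 bp nrDNA), not
the unmasked length — this convention is what makes every printed
(count, rate) pair mutually checkable as `rate = count / L`; rates over
the unmasked length are emitted as supplementary columns.  Pairwise
distances are p-distances over pairwise-unmasked columns, again per full
locus length, so `d(a, b) · L` is exactly the integer difference count.
Catchment-level distances are unweighted means over cross-catchment site
pairs; group rows (within-region, between-region) are unweighted means
over catchment pairs, with the implied SNP count `round(d̄ · L)`.  Display
strings use 2 significant figures in `1.3x10-3` style and percentages to
2 decimals; raw floats are always retained in machine output.

**4. Relationship tree.**  Neighbor-joining (Saitou–Nei) on the
catchment-level distance matrix.  NJ is exact on additive matrices, which
is the property the tests exercise; it replaces model-based Bayesian
inference because the tree's role here is visual representation of
distances, not topology estimation.  Ties on the Q criterion resolve to
the lowest pair of active-node indices; negative branch-length estimates
are clamped to zero and the total deficit recorded on the result.  The
stored tree is unrooted (anchored at the final trifurcation); midpoint
rooting is provided for display only.

## The generator

The simulator produces studies with the statistical structure the analysis
assumes, under two competing dispersal regimes:

* **founder_expansion** — all sites in a region descend from
  `n_founder_lineages` (typically 1) founding lineages; each site then
  accumulates private mutations for only `founder_age` generations.
  Predicts within-region homogeneity: no unique fixed SNPs per catchment,
  no between-catchment fixed differences, a short-branch cluster in the
  tree.
* **persistence** — each catchment in the region carries its own founding
  lineage, and lineages have diverged independently from the common
  ancestor for `lineage_divergence ≫ founder_age` generations.  Predicts
  catchment-private fixed SNPs and deep between-catchment distances.

Mutation is a Poisson point-substitution process: a branch of length `T`
generations over a locus of `L` sites receives `Poisson(μ·T·L)`
substitutions, each at a uniform position, to a uniform different base
(equal rates, no indels — the analysis surface is SNPs only, and repeat
hits are allowed, so expected pairwise divergence between two lineages is
≈ `2μTL` for short branches).  Individuals inherit the site haplotype
clonally (maternal, non-recombining).  Multi-copy nrDNA heterogeneity is
emulated by `ReferenceLocus.intra_individual_variants`: each individual
carries a Poisson-distributed number of private variant positions
(default 2.0 for the nrDNA locus, 0 for cpDNA), which surface as
within-pool variants at ≈ 1/pool_size frequency; at default depth this
puts detected within-pool counts in the 4–12 band typical of ribosomal
repeats.

Sequencing is compressed to a per-position channel: depth
`Poisson(mean_depth)`; each read copies a uniformly chosen pool member's
base, miscalled with probability `error_rate` (uniform over the other 3
bases), and lands on the forward strand with probability `strand_prob`.
Sampling is done in aggregate (multinomial over the induced per-base read
probabilities), which is distributionally identical to per-read
simulation.  Reads, qualities, mapping and assembly are deliberately not
modelled: the generator emits pileups directly.

Determinism: `generate_study(seed)` spawns every child stream from one
`numpy.random.SeedSequence` in a fixed order, so identical inputs give
byte-identical outputs.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `pool_size` | 8 | individuals/site | study convention; sets the 12.5% variant floor |
| `min_coverage` | 20 | reads | confirmation threshold; applied to total depth, not per strand |
| `min_variant_frequency` | 0.125 | fraction | 1/pool_size |
| `require_both_strands` | true | — | mechanized strand-support inspection |
| `mean_depth` | 60 | reads/position | comfortably above the mask threshold |
| `error_rate` | 0 (default config) | per base | the analysis conditions; set > 0 to stress the caller |
| `mutation_rate` | 1e-9 | subs/site/generation | plastid-like order of magnitude; illustrative |
| `lineage_divergence` | 2e6 | generations | with μ=1e-9 over 124,678 bp gives ~250 substitutions per lineage stem — hundreds of catchment-private SNPs, the regime of a deeply structured region |
| `founder_age` | 2,000 | generations | ~0.25 expected substitutions per site branch — near-total homogeneity with occasional singleton fixed SNPs |
| `intra_individual_variants` | 2.0 (nrDNA), 0 (cpDNA) | positions/individual | multi-copy repeat heterogeneity |

The rates and times are **illustrative**: no mutation-rate or
divergence-time estimates exist for the motivating system, so the defaults
are chosen to produce the qualitative contrast (homogeneous founder
region, hundreds of private SNPs per persistence catchment) at realistic
orders of magnitude, and are not calibrated to any species.  In the
default configuration the founder region's single lineage carries the
same stem divergence from the reference ancestor as the persistence
lineages, so between-region distances are comparable to within-persistence
ones — the star pattern seen in deeply structured organellar data.

### What the generator does not emulate

Read-level artefacts (quality decay, adapters, duplicates), mapping and
assembly error, reference bias, indels and structural variation,
recombination, selection, heteroplasmy, and depth autocorrelation along
the genome.  Passing tests therefore demonstrate correctness of the
calling/classification/summary logic under the stated generative
assumptions — not robustness to mapping artefacts in real libraries.

## Numerical and degenerate-input choices

* Frequency threshold comparison uses `freq ≥ threshold − 1e-12` so the
  exact boundary (e.g. 5/40 = 0.125) passes regardless of float noise.
* Zero-depth positions are masked (depth 0 < any min_coverage ≥ 1).
* `DistanceMatrix` validates symmetry, zero diagonal and non-negativity on
  construction; NJ requires ≥ 3 labels.
* Negative NJ branch estimates (non-additive input) are clamped to 0; the
  summed deficit is exposed as `RelationshipTree.clamped_deficit`.
* Columns with three or more segregating alleles: each non-consensus
  allele is tested against the caller thresholds independently; privacy is
  assessed on the union of non-majority carriers (the finest group
  containing all of them).
* Empty pileup files parse to empty pileups with a warning; malformed rows
  fail with the line number.

## Problem sizes in the shipped experiments

The default configuration simulates the full-length loci (124,678 +
5,813 bp, 12 pools, depth 60) and runs in seconds.  The test suite uses
0.8–30 kb loci: the founder/persistence recovery experiment runs one
30 kb locus across 12 pools; the divergence-monotonicity sweep runs 100
seeds × 3 divergence levels on a 2 kb locus with 3 single-site catchments;
caller–oracle equivalence enumerates 300 random ≤ 10-position pileups plus
a property-based suite; NJ exactness covers 100 random additive 4–5-taxon
matrices.  These sizes give comfortable Monte-Carlo resolution for every
assertion while keeping the whole suite in a few seconds.

## Known limitations

* No realignment: consensuses must share coordinates (true for simulated
  data; external data needs a prior MSA).
* The caller has no base- or mapping-quality model; `error_rate` is the
  only noise knob.
* Privacy attribution assumes every site is scored at analysable columns
  (guaranteed by masking propagation) and is undefined — reported as
  non-private — when a level has no outside site.
* NJ tie-breaking among exactly equal Q values depends on active-node
  order; on generic (continuous) matrices ties have measure zero, and the
  tests assert invariance of the tree up to isomorphism.
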