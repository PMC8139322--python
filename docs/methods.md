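# Methods

This note records the models, parameter choices and numerical
conventions behind `bacpan`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Synthetic pan-genome generator

**Tree.** Genomes are related by a rooted binary tree: either a Kingman
coalescent (pairs merge uniformly at random; exponential waiting times
with rate k(k−1)/2, giving a tree of height ≈ 2 coalescent units for
50 genomes) or a deterministic balanced topology with root-to-tip path
≈ 1. The coalescent is the default because its mix of long internal and
short terminal branches produces the broad accessory-frequency spectrum
(many rare families, some clade-wide ones) seen in real bacterial
clades.

**Gene content.** Core families are present in every genome by
construction. Accessory families follow a single-gain model in the
spirit of infinitely-many-genes: each family is gained exactly once, at
a uniform point on a branch (branch gains ~ Poisson(gain_rate × branch
length)), and is lost independently on each descendant branch segment
with probability 1 − exp(−loss_rate × length). A family lost before
reaching any leaf is never observed. This is a stand-in chosen for
transparency, not a fitted evolutionary model: it yields open
pan-genomes with tree-structured accessory sharing and is fully
determined by two rates.

**Calibration.** Defaults emulate a 52-genome species group with a
2,370-family core and ~3,700 genes per genome, the scale of the marine
and terrestrial *Bacillus pumilus* group the package targets. With
loss_rate = 1.0 per coalescent unit, gain_rate = 1,655 was calibrated by
simulation so the per-genome mean total is ≈ 3,670 (within 1% of the
target across replicate clades). The calibration trades realism in the
*pan-genome total*: the simulated pan (~14,000 families) is larger and
more dispensable-heavy than the real clade's (~9,400), because the
coalescent tree accumulates more mid-frequency accessory families than
the real phylogeny did. Tests that depend on per-genome totals or on
open/closed discrimination are insensitive to this; nothing in the suite
asserts the simulated pan-genome size itself.

**Niches and species.** By default the first `n_marine` genomes in tree
order are labelled marine — contiguous clades share a niche, mirroring
the tendency of marine isolates to cluster phylogenetically. A shuffled
mode assigns niches at random as a null. Species labels cut the tree
into `n_species` clades by repeatedly splitting the largest clade.
Planted niche-specific families are inserted into a random
⌈fraction × group⌉-genome subset of one niche and nowhere else.

**Proteomes.** Each family draws a random ancestral protein (uniform
over the 20 standard residues, length uniform on 100–400 aa; tests use
shorter ranges for speed). Each member genome receives an independently
mutated copy: per-site mutation probability q = 1 − √identity, mutating
to a uniformly chosen *different* residue, so the expected pairwise
identity between members equals the `identity_within_family` parameter.
Sequence divergence is therefore *star-shaped around the family
ancestor*: it carries no phylogenetic signal. Consequently the
concatenated-core distance tree on simulator output recovers star-like
topologies; the tree-recovery tests build clade-structured sequences
explicitly. Different families use independent random ancestors, keeping
inter-family identity at random-sequence background (≲25%, far below the
50% clustering floor).

**COG labels.** Each family gets one of 23 single-letter categories or
"unknown". The 23 letters are the standard set minus the A/B/X classes,
which are rare or absent in most bacterial annotations. Default weights
are shaped like a bacterial COG profile (metabolism and
information-storage heavy, ~17% unannotated). A skew option multiplies
selected categories' weights for a designated family set (for planting
enrichment signal); because the skewed vector is renormalised, a 2×
weight skew produces slightly less than a 2× observed frequency ratio
(≈1.87× at default weights), which the tests account for.

**Randomness.** One root seed; stage streams are derived via
`numpy.random.SeedSequence.spawn` in a fixed order (gene content, niche
shuffling, planting), so any stage is reproducible in isolation and all
emitted artifacts are byte-identical across runs with the same
configuration.

## Ortholog clustering

Pairwise protein similarity uses semi-global alignment (free end gaps)
with BLOSUM62 scores and affine gaps (open 11, extend 1). Identity is
matches / aligned columns, counted between the first and last aligned
pair (end gaps excluded); coverage is the aligned span over each
sequence's full length, and *both* sequences must reach the coverage
floor. Defaults are identity ≥ 0.50 and coverage ≥ 0.50. The `score_min`
floor stands in for a database-size-dependent E-value cut-off; its
default of 0 accepts any pair passing the identity/coverage floors,
which keeps the criterion deterministic and database-independent.

Families are connected components of a graph whose edges are
(a) inter-genome bidirectional best hits among passing hits — ties on
the best score are all kept — and (b) intra-genome passing hits
(in-paralogs). MCL-style inflation is deliberately not reimplemented;
on data where families are separated by a wide identity gap (the
simulator guarantees this; real proteomes usually do at 50%) components
equal the transitive closure of passing pairs, which the suite verifies
against a brute-force oracle. Family ids are assigned in lexicographic
order of (smallest genome id, smallest gene id) for reproducibility.

A shared-k-mer prefilter (k = 4, ≥ 1 shared, only applied to sequences
longer than 4k) skips clearly unrelated pairs before aligning. It is a
heuristic with no formal guarantee, so the suite checks directly that
families built with and without it coincide, including on pairs sitting
right at the 50% identity floor.

The distance phylogeny concatenates single-copy core families and uses
the pooled per-site mismatch fraction over aligned columns (a
p-distance) with neighbor joining; negative NJ branch lengths are
clamped to zero. This is a deliberate stand-in for a maximum-likelihood
tree — adequate for clade structure, not for branch-length inference.

## Pan-genome profile

Occupancy classifies families: all genomes → core, exactly one →
strain-unique, otherwise dispensable. With a single genome the core
class takes precedence over unique ("shared by all strains"). Fractions
are reported as percentages rounded to one decimal.

Rarefaction draws `n_permutations` (default 100) random genome orders
and records cumulative union (pan), intersection (core) and pan
increment (new genes). The *mean* trajectory across permutations is
fitted (the median is available via `PanProfile.summary`).

Curve fitting uses `scipy.optimize.curve_fit` with initialisation
A = range(y), γ = 0.5, C = min(y) for the power law and A′ = range(c),
k = 0.1, Ω = min(c) for the decays; bounds γ ∈ [0, 2], k ∈ [0, 5],
A, A′, Ω ≥ 0; up to 5 deterministically jittered restarts on failure,
returning a flagged non-converged result rather than raising. R² is
1 − SS_res/SS_tot, with the zero-variance convention R² := 1 when a
constant trajectory is fitted exactly. Constant input short-circuits to
the degenerate solution (amplitude 0, offset = mean) because the
3-parameter models are unidentifiable there. A pan-genome is called
*open* when γ > 0.01 (tolerance against numerical noise) with a
non-vanishing amplitude. The core model's printed exponent is read as a
decay, c(n) = A′e^(−kn) + Ω with k ≥ 0; the sign convention is
typographically ambiguous in the source material, and the decay reading
is the only one consistent with a shrinking core.

## Genome distance and species delineation

Sketches keep the s (default 1,000) smallest 64-bit hashes of canonical
(strand-minimum) k-mers (default k = 21); the hash is BLAKE2b truncated
to 8 bytes and keyed with the sketch seed, so sketches are bit-exact
across platforms. The Jaccard estimate uses the merged bottom-s
convention (shared hashes among the s smallest of the union), and the
Mash distance is d = −ln(2j/(1+j))/k, capped at 1 when j = 0. ANI-profile
correlation is the Pearson correlation of full matrix rows with
self-entries fixed at 100 (the common corrplot practice — recorded as an
assumption). Species are connected components of the ANI ≥ 95% graph;
the component rule is transitive by construction, so a chain A–B–C above
threshold is one species even if d(A,C) falls below it. An approximate
k-mer ANI (100·(1 − d)) is implied by the Mash distance but real ANI
matrices are consumed, not recomputed. Hierarchical dendrograms sort
labels before clustering (making output invariant to input order) and
emit branch lengths as merge-height differences, so ultrametric inputs
are reproduced exactly; UPGMA heights are half the cophenetic distances.

## Niche analysis and enrichment

Two selections are kept deliberately distinct:

* `shared_dispensable`: dispensable families present in *every* genome
  of a group, with **no** condition on the other group. Whether the
  published 397 marine-shared genes additionally excluded terrestrial
  carriers is ambiguous in the source; this function does not require
  background absence, and `niche_specific` carries the absence rule.
* `niche_specific`: present in ≥ ⌈fraction × |focal|⌉ focal genomes
  (default one third — the ceiling implements "at least one third" for
  indivisible group sizes) and in at most `max_background_presence`
  background genomes (default 0). Applied per species when species
  labels exist; species with fewer than two genomes in either niche are
  reported as "insufficient contrast" rather than an error.

Enrichment contrasts two family sets per COG category with the
two-sided Fisher exact test (2×2 table: category membership × set
membership; two-sided p sums all hypergeometric outcomes no more
probable than the observed one). No multiple-testing correction is
applied by default, matching the raw P < 0.05 convention of the
emulated analysis; Benjamini–Hochberg is available via
`correction="bh"`. Note that an exact conditional test is conservative
on sparse categories: under a shuffled-label null the overall flag rate
sits *below* α (≈0.03 at α = 0.05 with 500-family sets and the default
category weights) and approaches α only for categories populous enough
that the hypergeometric support is dense. The test suite asserts
exactly this: control everywhere, α-agreement on well-populated
categories.

## What the synthetic tests do and do not show

Passing the suite demonstrates that the algorithms implement their
definitions (verified against brute-force oracles), that planted signal
is recovered under the stated rules, and that open/closed pan-genomes
are discriminated over replicate clades. It does **not** demonstrate
performance on real proteomes: real data have fragmented genes, domain
shuffling, horizontal transfer between distant clades, paralog families
straddling the 50% identity floor, and annotation noise — none of which
the star-shaped mutation model or the single-gain/loss process emulate.
The clustering stage in particular is exercised only in the regime where
families are well separated in identity.

## Problem sizes in the test suite

Alignment-heavy tests run on clades of 4–5 genomes with 60–120 aa
proteins; rarefaction oracles enumerate ≤ 5-genome orderings
exhaustively; openness discrimination uses 20 replicate clades at the
full 52-genome default scale (matrix operations only); enrichment null
and power experiments use 100 replicates of 500-family sets. These sizes
were chosen so each oracle comparison stays exact while the full suite
remains a sub-minute run on a single core.
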