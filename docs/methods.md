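# Methods

## Parsimony age dating

A `CladeMap` is an ordered list of outgroup clades, oldest divergence first,
each carrying the branch label implied when that clade is the most distant
one retaining a syntenic ortholog.  `assign_age` scans the clades in order
and returns the first hit; a gene absent from every clade is assigned the
species-specific stratum br6.  Ages are capped at br-2: presence in the
deepest clade implies "at least br-2".  The dating core consumes a
gene × clade boolean presence matrix; producing that matrix (whole-genome
alignment, chaining/netting, reciprocal-best filtering, repeat masking) is
upstream of this package and out of scope.

The gene-loss correction takes a secondary deep outgroup at the same level
as a primary clade: genes dated to the younger branch but present in the
secondary outgroup are re-dated to the older branch, and the count moved is
usable as a deaths estimate for the younger branch's fixation rate.
`masked_exon_filter` retains genes whose masked-exon fraction is ≤ 0.70
(strictly greater is excluded).

Fixation rate = (births − deaths) / span.  Reported rates are rounded half
up to the printed precision (integer by default, one decimal where a rate
below ten is quoted); the raw float is always retained.  Branch spans are
configuration with defaults br0 = 7 MY, br1..br6 = 20/12/10/10/5/5 MY
(young total 62 MY); the split of br1–br5 is a configuration choice, as only
the br0 span, the young total and the terminal-branch span are fixed by the
calibration.

The sex-vs-autosome comparison is an uncorrected 2×2 chi-squared test
(young vs not-young × sex vs autosome); "uncorrected" keeps the statistic
equal to the textbook formula, which the tests use as an oracle.

## Localization calling and enrichment

A protein is called to every compartment with predicted probability
strictly > 0.5 (multi-membership allowed); the nine-compartment vocabulary
is the DeepLoc-2.0 set minus the plant-specific Plastid, and the three-level
grouping maps Extracellular → extracellular, Cell_membrane → cell membrane,
everything else → intracellular.  Proteins with an empty call set are
excluded from enrichment denominators and reported as a count — the source
analyses are silent on them, and including them would dilute every
expectation.  Expected counts are `total_c · n_b / N`, which conserve
compartment totals exactly when summed over branches.  Per-cell Fisher exact
tests are reported raw plus Benjamini–Hochberg adjusted.

Counting is protein-level with longest-transcript representatives used
wherever a single record per gene is required (tie on summed exon length
broken by smallest transcript ID).

## Co-localization resampling

Only single-compartment proteins participate.  For a target branch with m
proteins, Intra_num = C(m, 2) and co_intra counts same-compartment pairs.
Each of 100 iterations draws, without replacement, an equal number of
comparison pairs — from target × other-branch pairs (strategy A) or from all
pairs (strategy B) — and the iteration's excess is
(rate_intra − rate_inter)/rate_inter × 100 on the co-localization rates.
With the sample size equal to Intra_num this is identical to the count
formula; when a dominant branch makes Intra_num exceed the strategy-A pool,
the sample is capped at the pool size and flagged, and the rate form keeps
the statistic meaningful.  Iterations whose comparison sample has zero
co-localized pairs are excluded from the mean and counted.  The branch trend
is summarized by a Pearson regression of mean excess on branch index.

A caution that the tests encode: the excess statistic carries
dataset-composition noise of order 1/m beyond the iteration resampling
noise, because a finite branch's realized compartment mix is itself random.
Null calibration therefore uses label-permutation replicates of the same
dataset, not the iteration SE.

## Co-function expectation

p_co = Σᵢ P²(Kᵢ) with P(Kᵢ) the fraction of all annotated proteins on
pathway Kᵢ, single-membership arithmetic as defined for the expectation
(with multi-pathway proteins the sum can exceed the true pair probability;
kept as the normative simplification).  E = C(m, 2)·p_co per group, O counts
pairs with intersecting pathway sets (sparse incidence product), excess
= (O − E)/E.  Note the plug-in estimator Σ p̂² is biased upward by roughly
1/n, which can swamp a weak planted co-function signal; directional tests
therefore use designs where the planted effect is an order of magnitude
larger than this bias.

## Alignment, divergence and clustering

Global alignment is Needleman–Wunsch with affine gaps via
Bio.Align.PairwiseAligner, BLOSUM62, gap open −10, gap extend −1 (common
practice defaults; configurable).  Identity = identical columns / alignment
length, so gaps count against identity — the most conservative reading of a
global similarity; mutation positions are the 1-based column over the
alignment length for substitution columns (indel columns excluded by
default, includable by flag), binned into thirds with closed upper bounds.
Among co-optimal alignments the aligner's first traceback is taken; score
and identity are tie-break-invariant.

Clustering is a simplified greedy incremental scheme in the CD-HIT style
(threshold 0.5, word length 3): longest sequence first, each sequence joins
the first cluster whose representative it matches at ≥ 0.5 identity over
the shorter sequence, else founds a cluster; a shared-3-mer prefilter skips
alignments, and is part of the algorithm's definition (so the oracle replay
includes it).  CD-HIT's banded-alignment and word-statistics heuristics are
not reproduced.

Cluster divergence D is the mean over unordered member pairs of
(differing columns / columns where both sequences have residues) from
pairwise global alignments — a stand-in for a single multiple alignment;
within a 0.5-identity cluster the pairwise and MSA column sets agree
closely, and the oracle tests pin the implemented definition, which is
declared normative for this package.  Retained clusters need ≥ 2 members,
all single-localized to one shared compartment (the stricter reading, needed
to give the cluster a compartment; a flag relaxes it), and a compartment
needs strictly more than 40 surviving clusters to enter the comparison.
The age-constrained subset keeps clusters whose members are 100% within the
allowed age classes (default oldest + older).

## Interaction density and the WC/BC simulation

Links with combined score strictly > 700 form an undirected graph (reversed
duplicates merged, self-loops dropped and counted).  Density matrix:
diagonal (i,i) = edges with both endpoints carrying compartment i over genes
carrying i; off-diagonal (i,j) = edges joining i and j whose endpoint sets
do not intersect, over the union of the two gene sets — the union keeps the
diagonal and off-diagonal cells on one scale (the sum-of-sizes alternative
is behind a flag).  Multi-localized proteins contribute to every compartment
they carry; a single-localized mode restricts to unambiguous proteins.

The WC/BC simulation samples (by default) 50,000 interaction pairs, 50
times, splitting each sample into WC (endpoint compartment sets intersect)
and BC.  The per-sim per-gene frequency is the group's sampled edge count
divided by the distinct proteins incident to those edges; the two 50-value
collections are compared by a two-sided rank-sum test.  The exact
populations behind the source analysis's quoted p-value cannot be
reconstructed from its description; this package's definition is the one
documented here and no attempt is made to match that p-value.

## Paralog classification

Pairs are oriented by age (parent strictly older); equal-branch pairs are
excluded with a count.  The one-to-one filter drops any gene participating
in more than one pair, counting both columns.  Duplication age is ancient
exactly for parent br-2 with offspring br-1/br0 and parent br-1 with
offspring br0 — 3 of the 36 parent-older ordered branch pairs.  The
K/KE/S/E/SE rules partition all non-empty set pairs: K (equal), KE (parent
⊊ offspring), S (offspring ⊊ parent), E (disjoint), SE (partial overlap
with both gain and loss).  K-vs-non-K uses a one-sided (greater) rank-sum
on alignment identity and a two-sided rank-sum on pooled relative mutation
positions.

## The synthetic-data generator

Defaults emulate the study conditions: branch-birth weights follow the
published dated distribution (a br-2-heavy background, br0 ≈ 5%, young
branches at their reported ratios); compartment preference flattens with
age — the oldest class spreads broadly over intracellular compartments
while the young class concentrates on the extracellular space (45%);
multi-label rate 0.2; 10,000 physical links with within-compartment pairs
upweighted 5×; 50 pathways with a per-branch favoured pathway upweighted 2×
(boost 1 is exactly uniform); substitution rates 0.05/site with
Extracellular at 0.15 (the 3× contrast; a higher baseline would put
within-family identity at the 0.5 clustering threshold and dissolve the
clusters the divergence analysis needs); 300 paralog pairs with a
K-dominated pattern mix, non-K substitutions 80% concentrated in the
N-terminal third.

Presence matrices follow the birth branch exactly (a gene born on branch b
is present pre-loss in clades implying b or younger), with independent
per-clade loss flips; a secondary br-1-level outgroup series supports the
loss correction.  Called compartments get probabilities strictly above 0.5
and all others strictly below, so threshold calling is unambiguous by
construction.  Paralog patterns are realised by rewriting the parent's set
relative to the offspring's age-drawn set, so the branch-level preference
structure survives in the young classes; parents sit overwhelmingly in the
large deep branches where the rewrite is negligible dilution.

Each generator draws from `numpy.random.default_rng([seed, offset])` with a
fixed per-generator offset, so changing one generator's draw count never
perturbs another's output, and a fixed seed makes every table
bit-reproducible.

What the generator does **not** emulate: predictor calibration (probabilities
are not DeepLoc posteriors), realistic protein sequence composition or
length variation, genome coordinates beyond a minimal exon layout,
degree-heterogeneous interaction networks, non-uniform pathway-size
distributions, and the age-dependence of localization breadth (the
multi-label rate is a single scalar).  Passing tests therefore demonstrate
that the statistics recover planted structure of the stated kinds, not that
the biological effect sizes of any real dataset are reproduced; the
dataset-dependent headline figures of the source study (concordance with an
external age database, its exact K fractions, regression coefficients and
p-values) require the original annotations and are out of reach by design.

## Problem sizes and numerical choices

Tests and the acceptance script run at n = 2,000 genes (5,000 for the null
calibrations, 700 with a three-compartment design for the clustering-heavy
divergence analysis, sequence length 60–90, family size 2–3), 10,000 edges
with 5,000-pair samples, and 100 co-localization iterations — sizes chosen
so every directional effect is several standard errors strong while the
full suite stays fast.  Degenerate inputs are handled by flagging rather
than raising wherever a partial result is meaningful (empty branches,
zero-denominator iterations, compartments below the cluster minimum);
malformed input files always abort with a line-numbered parse error, since
silently skipping rows would corrupt the counts every statistic divides by.
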