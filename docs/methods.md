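# Methods

## Orthology by bidirectional best hit

Ortholog detection approximates orthology by the bidirectional-best-hit
(BBH) criterion: gene *g* in genome *G* is called an ortholog of seed *s*
iff *g* is the highest-scoring hit of *s* in *G* passing the thresholds,
and *s* is in turn the highest-scoring hit of *g* in the seed set.

Alignments are optimal Smith–Waterman local alignments under BLOSUM62
with affine gaps costing `open + k·extend` for a gap of length *k*
(defaults 11/1, the standard protein-search operating point).  The
alignment engine is biopython's `PairwiseAligner`; an independent
O(mn) Gotoh matrix fill lives in the test suite and the two are checked
against each other on random instances.  Non-standard residue letters are
mapped to `X` before alignment and never raise.

Significance uses the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with
the published gapped parameters for this scoring scheme (λ = 0.267,
K = 0.041); *n* is the total residue count of the searched proteome, so
E-values behave like per-genome database searches.  Bit scores are
`(λS − ln K)/ln 2`.  Two caveats are documented rather than hidden: the
Gumbel parameters are calibrated for natural sequence composition, and
for the small synthetic proteomes used in benchmarks the E-value at a
fixed raw score is far smaller than it would be against a real proteome.
The coverage filter (≥ 50% of query and/or subject aligned; `any` by
default, `both` available) is what keeps short spurious local alignments
out of the calls — the phrase "query and/or subject" is genuinely
ambiguous in the field, so both readings are exposed.

Best-hit ties break by raw score, then E-value, then lexicographic
gene id, making output independent of input order.  Exactly one hit is
retained per (seed, genome).

Fusion candidates are genes that are the forward best hit of ≥ 2 seeds
with subject spans overlapping by at most 10 residues (configurable);
two seeds hitting one shared span indicate a shared domain and are not
fusions.  The reverse BBH check necessarily fails for one half of a true
fusion gene (the gene's single best reverse hit can only be one of the
two seeds), which is why fusion detection operates on forward calls.

## Profiles

The species-level profile is binary (1 iff a BBH call exists).  Genus
consolidation replaces each genus's rows by the fraction of its genomes
carrying the ortholog, removing the over-representation of heavily
sequenced species.  Fractions are discretised into 11 levels: 0 and 10
are reserved for exact absence and exact fixation; interior fractions
round to the nearest tenth and clamp into 1..9, so a single carrier
genome in a large genus is never displayed as absence.  The reporting
convention rounds ensemble abundances to integer percentages; exact
fractions are kept alongside.  Aggregation conserves counts: genus
fraction × genus size sums to the species-level column sum, an invariant
asserted in the tests.

## Clustering

Distances are Pearson distances `d = 1 − r` on the genus-level interval
vectors (the quantity the profile heatmap displays; raw fractions are a
config option).  Correlation of constant vectors is undefined; the
package defines `r = 1` for element-wise identical vectors (the natural
`d = 0` limit for indistinguishable items — this is what lets genomes
lacking every seed protein, the endosymbiont pattern, group into one
clade) and the sentinel `r = 0` with a `ZeroVarianceWarning` otherwise.

Hierarchical clustering is unweighted average linkage (UPGMA on the
distance matrix), implemented directly because the package guarantees
platform-independent determinism that library implementations do not
specify: equal-height merges resolve toward the lexicographically
smallest pair of cluster representatives, and at every merge each
subtree is oriented so that the closest cross-junction leaf pair sits
adjacent (ties lexicographic), fixing the heatmap leaf order.  The
implementation is cross-checked in the tests against a naive O(n³)
recomputation and against `scipy.cluster.hierarchy` merge heights.

Discrete clusters come from CAST: open a cluster with the unassigned
element of maximal total affinity, then alternately ADD the outside
element of maximal mean affinity while that mean is ≥ t and REMOVE the
member of minimal mean affinity (self included) while that mean is < t;
close on stability (cycle detection guards the rare add/remove
oscillation).  The default affinity surface is the Pearson correlation
itself with t = 0.5.  A [0,1]-scaled surface `(r+1)/2` is available, but
on that scale t = 0.5 admits any positively correlated item, which
dissolves block structure whenever profiles share mild ensemble-wide
correlations; thresholding r directly at 0.5 matches the conventional
"affinity above 0.5" operating point and keeps moderately correlated
blocks (r ≈ 0.2) apart while co-occurring pairs (r ≥ 0.75) stay
together.

Single optimization fixes the genus order to a reference tree's leaf
order (phylogeny-subordinated clustering) and orders/clusters proteins
only.  Double optimization computes the protein axis first, preserves it
bit-for-bit, then orders genera by their own dendrogram and calls
repertoire clades with CAST on the taxa affinity matrix.  Clades are
numbered along the optimized row order.

Pair correlations "in the ensemble" are computed on the binary
species-level columns, where Pearson r equals the phi coefficient of the
2×2 co-presence table; the report flags the conventional 0.75–0.9
confidence band.  Profile clustering and the pair report therefore use
different surfaces (genus intervals vs species binaries) by design, and
both are exposed.

## Gene context

Contiguity is defined on annotation ranks, not nucleotide distance, and
ignores strand: genes form a contiguous block when they share a replicon
and rank-consecutive members have at most `max_gap` genes between them
(default 0; the option exists because survey statements about
"contiguous" genes sometimes tolerate one intervening gene).  Circular
replicons wrap.  `operon_runs` partitions a genome's called loci into
maximal runs; `location_summary` reports, per seed pair, co-presence
counts, the fraction contiguous when co-present, and the
chromosome/plasmid split.

## Synthetic data generator

The generator emulates the input shape of a genus-level profiling study:
a random binary genus tree; 20 genera of 2–6 genomes (defaults); for
each genome a proteome containing point-mutated descendants of the seed
proteins (uniform substitution at 15% per site by default, no indels —
score separation, not realistic evolution, is what the benchmark needs)
and 30 composition-matched decoys (shuffles of seed sequences, a harder
negative than uniform-random sequence).  Decoys are rejection-sampled:
a shuffle whose best E-value against any seed falls below 10⁻² (an order
of magnitude above the acceptance cut, at a generous database size) is
re-shuffled, because a decoy that aligns near threshold is not a valid
negative control and would corrupt the planted truth.  The bundled seed
sequences are synthetic stand-ins whose lengths echo the real proteins
(200–800 residues).

Presence structure is planted in co-presence blocks mirroring the
canonical clusters (PcoC-CueO-YebZ-CutF-CusF, PcoE-PcoD, PcoA-PcoB,
CusC-CusA-CusB-CopA, CueP alone).  Three repertoire clades — contiguous
segments of the tree's leaf order — each carry one core block
(B1/B3/B4) in every genome, up to a 2% per-protein dropout.  The two
remaining blocks are secondary: planted at the genus level, stratified
so every clade receives the same fraction of carrier genera (default
0.2) with carrier sets of different secondary blocks disjoint.
Stratification cancels, by construction, the correlation between a
secondary block and the clade-indicating cores; disjointness keeps
secondary blocks mutually anti-correlated.  Under these defaults
within-block phi is ≈ 0.95 and between-block correlations sit near or
below 0 — both well clear of the CAST threshold, which is what makes
planted protein clusters and repertoire clades exactly recoverable.  A
2% background activation adds the scattered exceptions real profiles
show; with small genera it occasionally (a few percent of generator
seeds) produces one genus whose mean affinity to its clade lands just
under 0.5 and is honestly left out by CAST — a boundary case, not a
failure of the method.

Planted operon blocks receive consecutive annotation ranks; fusion
plants concatenate two mutated seed descendants into one gene (forcing
co-presence in the carrier genome if needed).  Everything is a pure
function of the model (including its integer seed): identical models
emit byte-identical files.

What the generator does *not* emulate: indels, rate heterogeneity,
horizontal transfer, paralogous families, genome rearrangement and
nucleotide-level sequence.  Passing benchmarks therefore demonstrate
correctness of the pipeline's logic and its exact recoverability regime,
not performance on real proteomes.

## Calibration notes

The planted 2×2 co-presence table (p₁₁ = p₀₀ = 0.45,
p₁₀ = p₀₁ = 0.05) has closed-form phi = 0.8.  At 500 genomes the phi
estimator is unbiased with asymptotic sd 0.0268 (multinomial delta
method, matched by simulation), so a ±0.05 band is a 1.87σ interval
with ≈ 93.8% per-replicate coverage; checks demanding 95% coverage of
that band exceed what the estimator's sampling variance supports.

Problem sizes used in the test suite (one CPU): the end-to-end benchmark
runs 20 genera / ~79 genomes / ~44 proteins per proteome (~2 minutes,
dominated by ~50k local alignments); oracle-equivalence checks use 50
random BBH instances of ≤ 20 proteins and 100 random distance matrices
of ≤ 12 items.
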