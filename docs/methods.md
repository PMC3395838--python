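# Methods

## Motif model and scoring

A PWM stores per-position nucleotide probabilities in fixed A,C,G,T order.
Count matrices are regularized with a pseudocount distributed proportionally
to the background, `p = (c + k·bg) / (colsum + k)` with `k = 1` by default;
this is the weakest regularization that guarantees strictly positive
probabilities and hence finite log-odds. UNIPROBE matrices arrive as
probabilities with file rounding that breaks exact normalization; each
column is treated as 100 observations and passed through the same rule,
which simultaneously renormalizes and floors zeros. Scores are sums of
`log2(p/bg)` in bits against a zero-order background, uniform by default.
Windows containing gaps, N or any other IUPAC ambiguity code are
*unscoreable* — they raise a distinct signal rather than returning a number,
because no log-odds value is defined there.

## Exact calibration

The null law of the window score is computed exactly rather than sampled.
Each column's four weights are snapped once to a grid of `bin_width` (default
0.01 bits, so the discretization error of a window score is at most
`W·bin_width/2` — 0.05 bits for a typical 10-column matrix); the law of the
sum is then the convolution of the per-column laws, a dense
dynamic-programming pass over integer bins. The threshold `t_m` at target
p-value α (default 5×10⁻⁵) is the smallest grid score whose survival
probability is ≤ α; "p-value below α" is read as a non-strict tail bound
because the support is discrete and a strict inequality would be ill-posed
exactly at the attainable tail values. When even the maximum score has mass
above α the threshold is +∞ and the matrix can never produce a hit, which
the scanner honours by returning nothing.

The enumeration oracle (`brute_force_score_distribution`) walks all 4^W
windows over the *same* snapped weights, so the two independent computational
routes (convolution vs exhaustive enumeration) must agree bin-for-bin to
machine precision; their agreement is asserted in the test suite. Snapping
per column, rather than binning raw floating-point totals, is what makes
bin-level agreement well-defined: rounding a total can land in either of two
adjacent bins when column-wise rounding errors accumulate across the window.

The scanner performs all threshold comparisons on the same integer grid
(window score = sum of snapped column weights, hit iff ≥ the threshold bin),
so scan output is bit-reproducible against the calibration and "above t_m"
means ≥ t_m on the grid.

Under a uniform background, reversing the columns and swapping A↔T, C↔G is a
measure-preserving permutation of windows, so the reverse-complement matrix
has an identical null distribution and the forward threshold applies to both
strands; one calibration covers both scans.

## Promoter windows and conserved-site calling

Promoter regions are `[tss−flank, tss+flank)` (flank 3000 bp) clipped at
zero and the chromosome end, minus the union of coding intervals, with
windows of the same gene merged. Coordinates are 0-based half-open
throughout.

Scanning works in reference coordinates: the reference is the first MAF row,
and a candidate window is W consecutive ungapped reference bases. Every
required species' characters are read off the *same alignment columns* (the
columns carrying those reference bases); a gap or unscoreable character in
any required species disqualifies the position, since its score is
undefined. A hit requires score ≥ t_m in all required species with the same
threshold for each (the null model is the same background in every genome).
Both strands are scanned independently. A window inside overlapping promoter
intervals of several genes yields one hit per gene, because downstream
target sets are per-gene; a block missing a required species is skipped with
a logged notice rather than an error, mirroring how alignment coverage
varies along a genome.

## Enrichment and biclustering

For a PWM's target set T, an annotation term's gene set M and universe U,
the 2×2 table is `[[|T∩M|, |T∖M|], [|M∖T|, |U∖(T∪M)|]]` and the one-sided
("greater") Fisher exact p equals the hypergeometric upper tail of the
overlap. Scores are `−log10(f)`; the log base is a display convention that
cannot change biclusters after binarization. p-values are floored at 1e-300
before the logarithm to keep scores finite. Binarization keeps cells with
`f < p_threshold` (strict; default 1e-3, exposed as a flag).

BiMax enumerates inclusion-maximal all-ones submatrices by divide and
conquer: a template row with a partial ones-pattern splits the columns into
its ones (CU) and the rest (CV); any bicluster either lives inside CU
(first branch) or uses at least one CV column (second branch, enforced by a
mandatory-column set carried down the recursion; rows with no ones in the
branch's columns are dropped, which shrinks both branches and guarantees
termination). Leaves — submatrices whose surviving rows are all full — are
then deduplicated and checked exactly for maximality (a candidate is maximal
iff no outside row or column is all-ones against it); the recursion
guarantees completeness, the filter exactness. Output order is deterministic
(lexicographic by row then column set). Default size minima are 2×2: 1×k
biclusters are single-term or single-matrix trivia. An independent
exponential oracle enumerates row subsets with closure for cross-checking at
≤14 rows.

## Interaction graphs

Interaction records are typed (three TF→target provenances, miRNA→target,
kinase→substrate, ppi) and signed (activation / repression / ambiguous /
none). Defaulting rules: protein–protein records are undirected and
unsigned; miRNA records without a stated sign default to repression
(post-transcriptional silencing is the default assumption); other regulatory
records without a sign are ambiguous.

The compartment tree defaults to a pruned Cellular Component hierarchy —
cell → {extracellular region, plasma membrane, intracellular → {cytosol,
nucleus, mitochondrion, endoplasmic reticulum, Golgi apparatus}} — and is
user-overridable (parent-child TSV or OBO subset). A gene's annotated terms
map to themselves when in the tree, otherwise they walk up a supplied
ancestry to the nearest tree term; unannotated genes land in the generic
`intracellular` zone. One instance is created per (gene, compartment) pair,
and a record materializes an edge between *every* instance pair of its two
genes: an exhaustive presentation whose implausible combinations are left to
the intercompartmental filter, which removes undirected physical edges
between compartments that are neither identical, parent/child, nor listed in
a configurable adjacency set (by default only extracellular region ↔ plasma
membrane, the one membrane contact where a secreted/surface interaction is
physically plausible). Directed regulatory edges are exempt — regulation
acts through intermediaries and its endpoints legitimately sit in different
compartments.

Zones are nested rectangles computed from the tree (children tiled in a grid
strictly inside the parent with a 6% margin). Layout is an iterative force
simulation — pairwise inverse-square repulsion, springs on edges toward a
rest length, and a pull toward the compartment anchor that is constant
beyond a small softening radius and linear within it, so an isolated node
settles exactly on its anchor. Positions are clamped into the compartment
zone after every step: containment is guaranteed by construction, not by
force equilibrium. The simulation is deterministic given its seed and stops
after `iterations` (default 200) or when the largest displacement falls
below tolerance.

`common_interactors` expansion is read as the intersection — partners of
*all* selected genes — the stricter of the two readings of "common". SIF
export uses the relation vocabulary activates / represses / regulates /
binds / targets / phosphorylates; GraphML carries node attributes (gene,
compartment, position, regulatory-info flag) and edge attributes including
rendering hints (activation = green/arrow, repression = red/T,
ambiguous = violet/dot).

## Synthetic data

Generators are pure functions of their parameters and a seed (one
`numpy.random.default_rng` stream per invocation, no global state), so
reruns are byte-identical. The planted-alignment generator emulates
four-genome promoter alignments (hg, mm, rn, cf) at desk scale: background
columns are independent across species, planted windows carry the motif
consensus in every species with optional per-species mutation, and gaps land
only in non-reference species outside planted windows. Cross-species
independence is deliberately *not* a substitution model (no HKY/GTR, no
branch lengths): real alignments are correlated across species, which makes
random columns look more conserved than independent ones, so the synthetic
null is conservative for specificity claims but silent about the
false-negative behaviour a realistic phylogeny would induce. Passing tests
therefore demonstrate algorithmic correctness and calibration soundness, not
genome-scale performance; headline counts from genome-wide runs depend on
production alignments and annotation databases and are out of scope.

Default study conditions used by the validation suite and the acceptance
script: 4 species; 2,000-column alignments; width-10 motifs drawn from a
symmetric Dirichlet with concentration 0.05 (information content ≈ 16–19
bits, the high-information regime where footprinting is meaningful); target
p-value 5×10⁻⁵; 50 plant-free alignments for specificity; annotation
universes of 300–1,000 genes with background membership rate 0.02 and
planted 20-gene term/target associations; 8×8 density-0.4 matrices for the
BiMax/oracle cross-check and 20×15 density-0.1 matrices for planted-block
recovery; graphs of ≤200 instances for layout checks.

## Known limitations

- Zero-order background only; no Markov backgrounds or GC-stratified nulls,
  so GC-rich motifs will over-call in GC-rich promoters (the hits-vs-GC
  diagnostic table exists to surface exactly that).
- Negative-strand reference rows in MAF blocks are skipped rather than
  reoriented; UCSC promoter extracts put the reference on '+'.
- No annotation propagation up the GO graph; terms are tested as given.
- BiMax is exponential in the worst case; matrices from desk-scale
  enrichment runs (thousands of cells) are fine, dense genome-scale
  matrices may not be.
- The interactome module ships no database content; it consumes user
  flat files only.
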