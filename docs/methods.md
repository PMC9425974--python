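# Methods

This note documents the models and procedures implemented in `varcog`, the
parameter choices that matter, and what the synthetic-data experiments do and
do not demonstrate.

## Column homogeneity

For an alignment column of `N` residues `a_i` with weights `w_i`, every
candidate amino acid `x` from the 20-letter alphabet receives

    Q_x = Σ_i w_i · S(a_i, x)

where `S` is a symmetric integer substitution matrix. The consensus
`c = argmax_x Q_x` is calibrated against the expected score of a random
residue assortment, `Q_R = Σ_b f_b · Q_b`, with background frequencies `f_b`:

    h = max((Q_c − Q_R) / (S_cc − Q_R), 0)

so that `h = 1` exactly for an invariant column and `h = 0` for a column
indistinguishable from (or worse than) chance. The quantity is bounded above
by 1 because `Q_c ≤ S_cc` whenever the matrix is maximal on its diagonal
(true of BLOSUM62; asserted empirically over fuzzed columns in the suite).

Choices:

* **Weights** are equal (`1/N`) by default; an externally supplied vector
  summing to 1 is accepted. No similarity-based weighting scheme is applied.
* **Gaps** carry no score: weights are renormalized over the non-gap rows of
  each column. Columns with fewer than two non-gap residues cannot express
  diversity and are masked — zero residues as `skipped-all-gap`, one as
  `skipped-singular` (a singular insertion).
* **Ambiguous residues** (B, Z, X, U, O, J) are treated as gaps: matrix files
  do not guarantee scores for them, and this keeps behavior deterministic
  across matrices.
* **Consensus ties** go to the alphabetically first amino acid, with a 1e-9
  tolerance on score comparisons. Genuine score differences are multiples of
  the weight resolution times integer score steps — far larger — so the
  tolerance only absorbs floating-point summation-order noise on exact ties.
* **Substitution matrix**: built-in BLOSUM62 by default; any NCBI-format
  matrix text file can be supplied. **Background frequencies** default to
  the Robinson–Robinson table (shipped as `data/robinson_frequencies.tsv`,
  normalized to sum 1 on load); the table used is recorded in the score
  model's metadata, and any 20-row TSV can be substituted.

Families qualify for analysis with ≥ 8 non-identical sequences (exact
equality of ungapped residue strings after duplicate removal) and ≥ 60
informative columns. An informative column draws non-gap residues from at
least two sequences; singular insertions and all-gap columns do not count.

## Relative variability

With `h_C` the mean homogeneity over a family's scored columns and `h_T` the
clade-wide mean,

    v_C = (1 − h_C) h_T / ((1 − h_T) h_C),     0 < h_C ≤ 1, 0 < h_T < 1.

`v = 1` exactly when `h_C = h_T`; `v = 0` iff the family is perfectly
invariant. Families with `v < 0.5` are classified conserved and `v > 2`
variable; the boundary values 0.5 and 2.0 fall in the intermediate class
(the outer classes are defined by strict inequalities). The same transform
applies per column (raw, unsmoothed `h`), yielding position classes and their
per-family fractions; a column with `h = 0` receives an arbitrarily high
variability, reported as a finite configurable sentinel (default 1e6) with a
flag so TSV output stays numeric.

`h_T` is the arithmetic mean over **all scored columns pooled across the
clade's families** (column-weighted), not a mean of family means: the pooled
mean is the baseline that position-level variability shares with
family-level variability. A `mean_of_means` mode is available.

Feature bins used in reporting: paralogy (proteins per covered genome)
[1, 1.25) low / [1.25, 3) medium / ≥ 3 high; gain rate [0, 0.5) low /
[0.5, 2) medium / ≥ 2 high; membrane or secreted when the respective protein
fraction is ≥ 1/3.

## Homogeneity-distribution geometry

Profiles are smoothed along the alignment with a Gaussian kernel of
bandwidth `b = 20` positions:

    h_i' = Σ_j h_j K_ij / Σ_j K_ij,   K_ij = exp(−((j − i)/b)²),

truncated at the profile ends (the normalization absorbs the edge effect)
and skipping masked columns. The smoothed values are converted to a density
on 101 equidistant grid points over [0, 1] by Gaussian KDE with Silverman's
bandwidth, boundary-reflected at 0 and 1 and renormalized to unit mass; a
zero-variance profile degenerates to a unit spike at the nearest grid point.
Note that boundary reflection deliberately accumulates mass at the support
edges: a tight mode within one bandwidth of 0 or 1 will present as a
boundary mode, which is the correct bounded-support behavior, not an
artifact. A histogram estimator is not provided; the estimator name is
recorded in the density metadata.

Distributions are compared with the discrete Hellinger distance on the
unit-mass grid vectors,

    d(P, Q) = sqrt(1 − Σ_i sqrt(p_i q_i)) ∈ [0, 1],

(unit-mass normalization is what confines the distance to [0, 1]), and
embedded by classical (Torgerson) MDS: double-center the squared distance
matrix, `B = −½ J D² J`, eigendecompose, and take coordinates from the top
positive eigenpairs. Negative eigenvalues — present whenever the distances
are not exactly Euclidean — are truncated but reported in full for
inspection.

## csCOG extraction from gene trees

Within a gene tree whose leaves come from `S` distinct genomes, a clade with
`P_C` leaves from `S_C` genomes has paralogy ratio `P_C/S_C`, coverage
`S_C/S`, and tradeoff index `S_C²/(P_C·S)`. Extraction repeatedly removes
the maximal-index clade (suppressing the resulting unifurcation) until the
maximum sits at the root, at which point the remaining tree is the final
csCOG. Design points:

* `S` stays frozen at the original tree's genome count across rounds, so
  coverage is comparable between rounds (per-round recomputation available
  by flag).
* Leaves are eligible clades (index `1/S`), so orphan sequences can come out
  as singleton groups; a minimum clade size is configurable.
* Ties are broken deterministically: larger `S_C`, then smaller `P_C`, then
  earlier post-order position.
* Unrooted inputs (basal multifurcations) are midpoint-rooted on load.

The index intentionally tolerates sporadic paralogy: duplicating a small
subtree barely lowers the root's index, so such copies stay inside one
inclusive group, whereas clade-wide duplications (high paralogy ratio at the
root) are split into the duplicate copies. Synthetic-recovery experiments
therefore plant whole-tree duplications.

## Gain/loss interpretation

Given a rooted species tree and per-node posteriors of presence, the edge
difference Δ = P(child) − P(parent) is a discrete gain when Δ ≥ 0.5 and a
loss when Δ ≤ −0.5. Continuous totals sum positive and negative differences
separately. Origination is modeled as a virtual edge into the root from
absence (parent probability 0): a root posterior ≥ 0.5 contributes one gain,
and the gain total includes the root posterior; both totals are also
reported without the root term so either convention is recoverable. A family
is *ancestral* when the root posterior is ≥ 0.5 (boundary inclusive);
otherwise the gain event closest to the root classifies it as *intermediate*
(internal edge) or *terminal* (leaf edge) acquisition, with ties at equal
depth resolved toward internal edges; families with no gain event are
*unclassified*. On binary (0/1) posteriors these rules recover a simulated
event history exactly, which the suite asserts on seeded replicates.

## Microsatellite-like regions

In i.i.d. random sequence over an alphabet of size `A`, the occurrence count
of a fixed k-mer among the `t = L − k + 1` start positions of an
`L`-character window is Binomial(t, p) with `p = A^−k`. A recurrence count
`n` is non-random at level α when the upper tail P(X ≥ n) < α. With α =
10⁻⁶ and A = 4 this yields the hexamer ladder: ≥ 6 occurrences in 1000 bp,
≥ 5 in 500, ≥ 4 in 200, ≥ 3 in 80. The trials convention `t = L − k + 1`
is what reproduces this entire ladder, including the borderline 80-bp case
(tail 9.70×10⁻⁷).

The scanner collects, for every k in 1..6 and every distinct k-mer,
occurrence runs: maximal chains whose consecutive start-to-start intervals
satisfy `I ≤ k` (overlapping motifs allowed; non-ACGT characters never occur
inside motifs and hence break runs). A run is significant when its count
meets the binomial threshold for its own span, clamped to the [80, 1000]
window range:

* the 1000-character cap keeps the test local (runs longer than the cap are
  judged per sliding 1000-character window);
* the 80-character floor — the smallest scale of the ladder — prevents the
  selection effect of judging a 2-occurrence run against its own
  few-character span, where any 7-bp homopolymer (a ~2×10⁻⁴-per-position
  event in random sequence) would otherwise pass a nominal 10⁻⁶ test.

Significant run footprints (`[start, start + k)` per occurrence) are merged
across motifs and k whenever separated by less than the motif length (the
larger k of the pair decides), and the per-gene MSR fraction is merged
coverage over sequence length; family summaries average member fractions.

An irreducible detection floor remains: any scanner sensitive enough to
recover 8-unit mononucleotide arrays (8 bp) must also flag chance 8-bp
homopolymer runs, which occur at a rate of about (3/4)·4⁻⁷ per position —
roughly 9 expected per 200 kb of random sequence. The measured background
under the defaults is ~0.08 merged regions per random kb.

## Synthetic fixtures

* **Families**: a star-tree substitution model — a consensus drawn from the
  background distribution; each of `n_sequences` copies substitutes each
  site independently with probability θ, drawing replacements from the
  background (possibly the consensus itself, so the expected fraction of
  changed sites is slightly below θ). Defaults: 10 sequences × 100 columns,
  matching the inclusion filter with headroom. This induces controlled
  column homogeneity but no phylogenetic correlation, rate variation or
  indels; passing rank-recovery tests (Spearman ≥ 0.95 between θ and v over
  20 families per θ level on a grid from 0.05 to 0.6) demonstrates monotone
  calibration of the variability scale, not realism of the evolutionary
  model.
* **Gene trees**: random rooted topologies by iterative joining, with
  whole-subtree duplications at random nodes (or at the root); the true
  partition tracks copy tags. Branch lengths default to 1 where needed for
  midpoint rooting.
* **Presence histories**: a two-state Markov process down the tree with
  per-edge gain/loss probabilities, emitted as 0/1 posteriors with the exact
  event list.
* **Planted repeats**: uniform random nucleotide background with a tandem
  array inserted at a known interval.

All generators are deterministic under their seed.

## Problem sizes and numerical conventions

The test and acceptance experiments use desk-scale sizes chosen to exercise
every code path with tight statistical margins: 1000 fuzzed columns against
the brute-force homogeneity oracle (1e-12), 50 random ≤ 12-leaf trees
against the exhaustive extraction oracle (exact partition match), 120
simulated families for divergence-rank recovery, 100 seeded gain/loss
replicates, 200 random 1-kb sequences for the false-positive census, and
100 random density triples for the Hellinger metric axioms. Coordinates in
all outputs are 0-based half-open. Eigendecompositions symmetrize their
input before `eigh`; density masses are clipped non-negative and
renormalized; the Hellinger Bhattacharyya coefficient is clamped to [0, 1]
before the square root.

## Known limitations

* Equal sequence weights only; no tree-aware or redundancy-aware weighting.
* The homogeneity scale depends on the chosen background table; switching
  tables shifts `Q_R` and hence absolute `h`, though clade-relative `v` is
  far less sensitive.
* The KDE bandwidth is global (Silverman); sharply multimodal smoothed
  profiles near the support boundary resolve as boundary modes.
* csCOG extraction assumes the gene tree is correct; it has no confidence
  model for weakly supported clades.
* The MSR scanner's per-run significance is a screening statistic, not a
  multiplicity-corrected test; genome-scale scans should expect the
  background rate quoted above.
* Ancestrality subclasses (intermediate vs terminal) depend on the
  deepest-gain-edge rule; other operational definitions are possible.
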