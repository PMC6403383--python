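# Methods

## Sequence model and estimation

A DNA sequence is modelled as a realisation of a first-order
homogeneous Markov chain on S = (A, T, G, C). The 1-step transition
matrix is the maximum-likelihood estimate from adjacent-pair counts:
p_ij = N(s_i s_j) / Σ_j N(s_i s_j). The k-step matrix is the k-th matrix
power (Chapman–Kolmogorov), computed by iterated multiplication — at
4×4 with k of a few tens this is exact to machine precision and avoids
eigendecomposition edge cases; rows are renormalised by their
(near-unit) sums so stochasticity holds to 1e-12 at every step.

Two conventions deal with inputs the estimator cannot use directly:

- **Ambiguity codes and gaps.** Non-A/C/G/T symbols (N, Y, M, gaps,
  stray whitespace) are removed, but each removal is recorded as an
  *adjacency break*: a dinucleotide is counted only if its two residues
  were literally adjacent in the raw input. This avoids fabricating
  pairs across unknown bases. RNA input is mapped U→T.
- **Zero rows.** A state never observed as a pair start (possible in
  short sequences) has no defined outgoing distribution. The default
  policy sets that row to uniform (0.25 each); an alternative
  `pseudocount` policy add-one-smooths the whole count grid. Both keep
  the matrix row-stochastic.

## Fuzzy-integral similarity

For two k-step matrices P1, P2, per cell y_ij: evidence
h(y_ij) = 1 − |P1_ij − P2_ij| and density μ(y_ij) = max(P1_ij, P2_ij),
the conservation level of that pair, so well-conserved positions carry
more weight. Per row i, the four densities induce a λ-fuzzy (Sugeno)
measure — μ(X∪Y) = μ(X) + μ(Y) + λ_i μ(X)μ(Y) for disjoint X, Y — with
λ_i > −1 fixed by the normalisation Π_j(1 + λ_i μ_ij) = 1 + λ_i. The
row score is the Sugeno integral max_j min(h_(j), μ(A_ij)) with h
sorted descending and A_ij the cumulative sets; similarity is the
maximum of the four row scores, distance D = 1 − similarity.

Numerical choices:

- **λ root finding.** Row densities are elementwise maxima of two
  stochastic rows, so Σμ ≥ 1 and the normalising root lies in (−1, 0)
  (λ = 0 exactly when Σμ = 1 within 1e-9, the additive case). The root
  is bracketed by bisection on [−1+1e-12, −1e-12] to an interval below
  1e-14 (≤ 200 iterations), then polished by a few Newton steps; the
  residual of the normalisation is then at machine precision. For
  completeness Σμ < 1 (λ > 0) is handled with an expanding bracket.
- **Degenerate densities.** Exact 0/1 patterns (e.g. rows of
  deterministic matrices estimated from repetitive sequences) admit
  only the trivial roots 0 and −1. The solver falls back to λ = 0 and
  the cumulative measure is clamped at 1, which restores the
  fuzzy-measure axiom μ(full set) = 1 and keeps the integral
  well-defined and monotone. The clamp engages only in this fallback.
- **Tie-breaking.** Sorting h within a row uses a stable sort, so tied
  evidence keeps the original column order (A, T, G, C). The integral
  value is invariant to tie order; stability makes intermediates
  bit-reproducible, and the similarity is bit-exactly symmetric in its
  two arguments.

Note that aggregating rows by their maximum (as the integral's outer
operation) means two matrices are similar as soon as *one* row matches
well; in particular two sequences that both lack some nucleotide as a
pair start share a uniform fallback row and score distance 0 at k = 1.
This is intrinsic to the aggregation, harmless for realistic sequences
(all 16 pairs present), and worth knowing for adversarial toy inputs.

## Optimal step selection

The distance matrix D_k is computed for k = 1, 2, … and the search
stops at the smallest h with RMSD(D_h, D_{h+1}) ≤ tol, where the RMSD
runs over the strict upper triangle (the diagonal is identically zero
and would dilute the statistic). Matrix powers of ergodic chains
converge geometrically to their stationary rows, so D_k stabilises and
the search terminates quickly; at the optimal step the matrices are
near-stationary, i.e. the distances chiefly compare the chains'
stationary (compositional) structure. The idealised criterion is exact
equality of consecutive matrices; in floating point a tolerance is
required, and the default tol = 1e-6 matches the 6-decimal PHYLIP
serialisation of the matrices. The search is capped at max_k = 30;
hitting the cap is reported as a flagged, non-converged result rather
than an exception.

## Trees and evaluation

UPGMA (rooted, ultrametric, size-weighted average linkage) and
Saitou–Nei neighbor joining (unrooted; negative branch-length estimates
clamped to zero with a warning) are implemented natively so the toolkit
has no binary dependency; the PHYLIP square-matrix writer (strict
10-character names by default, relaxed full names on request) lets
users cross-check with PHYLIP's own programs. Agglomeration ties are
broken by the lowest cluster-index pair and the merged cluster takes
the lower index's position, so output is deterministic and independent
of input permutation up to tree isomorphism. Trees are dendropy objects;
Newick serialisation and Robinson–Foulds comparison (on unrooted
bipartitions; rooted inputs are unrooted first) go through dendropy.

ROC/AUC evaluation scores every unordered taxon pair by similarity
(1 − distance) with within-group pairs as positives under a
user-supplied grouping; the curve is a threshold sweep and the AUC the
trapezoid rule (scikit-learn), which equals the tie-aware normalised
Mann–Whitney statistic.

## Synthetic data: what it emulates and what it does not

`simulate_sequence` draws exact realisations of a specified chain.
`evolve_family` simulates a root sequence and evolves it along a guide
tree: per branch, each site mutates independently with probability
1 − exp(−rate·length), to one of the other three bases uniformly
(Jukes–Cantor-like). All randomness flows from explicit integer seeds.

The bundled family benchmark (used by the recovery tests and the
acceptance script) is 8 leaves, 20 kb, rate 1.0 per unit branch length,
root chain A/G-rich and fast-mixing (second eigenvalue ≈ 0.12), guide
tree balanced with cherry depths 0.17 / 0.25 / 0.60 / 0.79. The depth
variation is deliberate: under uniform substitution every lineage's
composition relaxes toward uniform at a rate set by its path length, so
on a strictly clock-like tree all leaves share the same *expected*
composition and the only clustering signal at the (near-stationary)
optimal step would be sampling drift, which at 20 kb is of the same
order as estimation noise. Varying clade depths instead gives clades
distinct heritable compositional signatures — the lineage-specific
composition bias that word-statistic methods exploit in real genomes.
Consequences for interpretation: passing the benchmark shows the full
pipeline turns compositional divergence into the correct topology under
realistic noise; it does not exercise indels, rearrangements, rate
heterogeneity across sites, or within-clade compositional convergence,
all of which real genomes have and the generator deliberately omits.

## Problem sizes and defaults

Tests and the acceptance script use 20 kb × 8 sequences × 20 replicates
for the end-to-end benchmark, 100 kb for parameter recovery, and 1000
random rows for the integral/λ checks — sizes at which every stochastic
margin in the checks is wide (e.g. parameter recovery error ≈ 0.005
against a 0.01 bound). Key defaults: zero-row policy `uniform`,
convergence tol 1e-6, max_k 30, tree method UPGMA, strict PHYLIP names
of width 10.

## Known limitations

- The row-maximum aggregation makes the distance insensitive to rows
  that match poorly when another row matches well (see above).
- The distance is not a metric in the mathematical sense (no triangle
  inequality guarantee); it is used only as input to distance-based
  clustering, as intended.
- Sequences shorter than a few hundred bases give noisy transition
  estimates; the uniform zero-row fallback can then dominate.
- The method compares compositional/transition structure; it carries no
  positional information and cannot separate taxa whose genomes differ
  only by large-scale rearrangement of identical composition.
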