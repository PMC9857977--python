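# Methods

## The sorting problem

A binary matrix **B** (rows = genes or other binary features, columns =
samples) exhibits *mutual exclusivity* when a group of rows rarely share
non-zero entries in the same column — in cancer genomics, genes of one
pathway that are almost never co-mutated in the same patient. A *run* is a
maximal block of consecutive 1s within a row. Mutual-exclusivity sorting
reorders rows and columns so that runs are long and do not overlap
vertically; finding the optimal arrangement is NP-hard, so `mutexsort`
implements a deterministic greedy heuristic.

## The two-phase heuristic (`mutex_sort`)

**Phase 1 — row order.** All genes and samples start uncovered. While both
uncovered genes and uncovered samples remain, the *best-in-class* gene g\*
maximizes the exclusive coverage

    score(g) = Σ_{s ∈ S} ( B[g,s] − Σ_{g' ∈ G, g' ≠ g} B[g',s] ),

with S the uncovered samples and G the uncovered genes. g\* is appended to
the covered-gene vector G\* and its uncovered mutated samples become
covered. When samples run out first, the remaining genes are appended in
original order. Because the subtraction term is constant in g, score(g) =
2·cov(g) − T with cov(g) the gene's coverage of uncovered samples and T the
total 1s of the uncovered submatrix; the argmax therefore coincides with
the most-covering gene — a greedy maximum-coverage (set-cover–style) rule.
The implementation exploits this identity for speed but reports the printed
score; an alternative reading, where the penalty only counts samples in
which g itself is mutated, is available as `variant="restricted"`
(`--bic-variant restricted`) for sensitivity analysis and is off by
default.

**Phase 2 — column order.** Samples are reset to uncovered. Visiting genes
in G\* order, each gene's uncovered mutated samples are appended sorted by
decreasing per-sample exclusive coverage

    L_s = B[g,s] · (1 − Σ_{g' ≠ g} B[g',s]),

where the competitor sum runs over the whole gene queue. Columns never
claimed (e.g. all-zero columns) go last in original order.

**Tie-breaking and determinism.** Ties are always resolved by original
row/column position (stable sorts, first-index argmax). The algorithm uses
no randomness; repeated runs are bit-identical. Complexity is
O(n²m + nm·log m); a permutation matrix is the worst case for phase 1
(one row and one column covered per iteration).

## The MEMo comparator (`memo_sort`)

Rows are sorted by decreasing marginal; columns by decreasing value of
their 0/1 pattern read top-to-bottom as a number in binary notation (top
row = most significant bit). Column comparison is implemented
lexicographically on the bit sequences, which is exactly equivalent to
comparing the 2^n-scale integers without overflow at any n; tests verify
this against an arbitrary-precision integer oracle up to n = 30.

## Evaluation scores (`scoring`)

* **Overall mutual-exclusivity coverage** — iterate rows top to bottom;
  each gene scores the phase-1 formula over the not-yet-deleted submatrix,
  then the gene and its remaining mutated samples are deleted; the total
  (possibly negative) is a pure row-ordering score, invariant under column
  permutation. On the n×n identity in natural order it telescopes to
  n − n(n−1)/2.
* **Joint entropy** — the empirical (plug-in) joint Shannon entropy, in
  nats, of a pair of binary rows over the four outcomes, 0·ln 0 = 0. For
  equal marginals c ≤ m/2, disjoint supports strictly beat identical
  supports. `topk_pair_entropy` averages it over all C(k,2) pairs among the
  first k rows of a sorted matrix (k = 10 in the benchmark).
* **Run statistics** — per-row run counts and mean lengths plus the
  consecutive-row overlap Σ_i #{j : B[i,j] = B[i+1,j] = 1}; diagnostics
  only, not optimized directly.
* **Pair ranking** — a known gene pair "lands in the top k rows" only when
  both members do, so its rank is the worse of the two positions.

## Synthetic generators (`synthetic`)

* `random_bm(n, m, density, seed)` — iid Bernoulli(density) entries; an
  `exact_count` mode places exactly ⌊nmd⌋ ones uniformly instead.
* `shuffled_diagonal(n, seed)` — a shuffled permutation matrix (density
  exactly 1/n); the sorter provably restores the identity matrix from it,
  verified exhaustively over all n! permutations for n ≤ 6.
* `inject_patterns(spec)` — background Bernoulli(density) rows plus 10
  (configurable) mutually exclusive rows and 10 co-occurrent rows at random
  row positions, with ground-truth labels.

**Injection defaults.** The mutually exclusive rows get pairwise-disjoint
supports that partition the entire sample set (`me_ones = m // n_me`) —
the strongest form of exclusivity and the densest that 10 disjoint rows
can be. The co-occurrent rows carry the *same* marginal as the ME rows,
with ~90% of it in a shared core (`cooc_noise = max(1, me_ones // 10)`,
`cooc_core = me_ones − cooc_noise`). Matching the marginals is deliberate:
the plug-in joint entropy of a row pair grows with row density (below 0.5
per-cell mass), so unequal densities would turn the entropy benchmark into
a density comparison; with matched marginals it isolates exclusivity
versus overlap. All counts are overridable per spec field.

**What the generator does not emulate:** real mutation data have
heterogeneous per-gene frequencies, patient subtypes, and correlated
passenger noise; the background here is homogeneous iid. Passing
benchmarks on these matrices shows the sorters separate planted structure
from iid noise, not that they resolve every real-data pattern.

## Benchmark harness (`bench`)

For each (size, density, replicate) a fresh matrix is generated from a
seed derived from the master seed; every requested method sorts it and the
sorted matrix is scored. Consecutive method pairs are compared with a
one-sided paired Wilcoxon signed-rank test (H1: left > right), zero
differences dropped, exact null for ≤ 25 non-zero differences and normal
approximation with continuity correction above; an exact/Monte-Carlo
sign-flip permutation test is available (`method="signflip"`). Win
fractions accompany every p-value. The random baseline shuffles rows only,
leaving columns fixed. Timing sweeps are informational and never asserted
— wall-clock values are hardware-dependent.

**Problem sizes.** The default suites use 100×100 matrices (200 replicates
per density) for the coverage benchmark and 200×200 matrices (100
replicates per density) for the entropy benchmark, with the full-scale
1000×1000 / 1000-replicate design reachable through `SweepConfig` or the
CLI's YAML config. These sizes were chosen so the whole benchmark runs in
seconds on a single CPU while keeping every paired comparison far past the
p < 10⁻⁴ level where the methods genuinely differ.

## Known limitations

* On the coverage score, the greedy heuristic dominates the comparator and
  the unsorted baseline at every tested size and density.
* On the entropy score, the ranking heuristic > MEMo > random holds at
  background densities 0.01 and 0.05 but **not at 0.1**: ten disjoint rows
  can carry at most m/10 ones each, so at background density 0.1 the
  injected exclusive rows can no longer exceed the background marginals
  (pigeonhole), and since the plug-in joint entropy increases with row
  density, plain marginal sorting mechanically tops the entropy ranking
  there. This is a property of the score and the injection geometry, not
  of the implementation; the corresponding test documents the boundary and
  is expected to fail at that density.
* The coverage score is the quantity the heuristic itself greedily
  optimizes, so coverage comparisons favour it by construction; the
  entropy score is the independent check.
* All-zero rows and columns are legal and end up in the leftover blocks;
  empty matrices are rejected at construction.
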