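# mutexsort

Mutual-exclusivity sorting of binary genomic matrices.

Binary (0/1) matrices summarize genomic events — somatic mutations, copy
number alterations, gene essentialities — across cohorts of patients or
cell lines: rows are genes, columns are samples. A set of genes belonging
to one oncogenic pathway often shows *mutual exclusivity*: each sample
carries an alteration in at most one of them. Defining a **run** as a
maximal block of consecutive non-zero entries within a row,
mutual-exclusivity sorting reorders rows and columns so that runs are long
and do not overlap vertically, which makes such patterns visible in an
oncoprint-style display. Finding the optimal arrangement is NP-hard;
`mutexsort` provides a fast deterministic greedy heuristic, the classic
MEMo sorting procedure as a comparator, evaluation scores, synthetic-matrix
generators with planted ground truth, and a benchmark harness.

## The algorithm in brief

Phase 1 picks rows greedily: the *best-in-class* gene g\* among the
uncovered genes G over the uncovered samples S maximizes

    score(g) = Σ_{s∈S} ( B[g,s] − Σ_{g'∈G, g'≠g} B[g',s] )  =  2·cov(g) − T,

so each step selects the gene covering the most still-uncovered samples
(ties: original order), covers its samples, and appends it to the row
order G\*. Phase 2 orders columns: visiting genes in G\* order, each
gene's still-unclaimed mutated samples are appended sorted by decreasing
exclusive coverage L_s = B[g,s]·(1 − Σ_{g'≠g} B[g',s]). The comparator
(`memo_sort`) instead sorts rows by decreasing marginal and columns by
their 0/1 pattern read as a binary number (top row = most significant
bit). Scores, generators and the statistics of the benchmark are described
in [docs/methods.md](docs/methods.md).

## Worked example

```sh
$ cat demo.tsv
        s1  s2  s3  s4
g1      1   1   0   0
g2      0   0   1   1
g3      1   0   1   0

$ mutexsort sort --input demo.tsv --output sorted.tsv --orders orders.json
sorted 3x4 matrix with method=mutex -> sorted.tsv

$ cat sorted.tsv
        s2  s1  s4  s3
g1      1   1   0   0
g2      0   0   1   1
g3      0   1   0   1

$ mutexsort score --input sorted.tsv --metric coverage
{"metric": "coverage", "value": -1}
```

Phase 1 keeps the row order (g1, g2, g3): all three genes tie at score
2·2 − 6 = −2, g1 wins by original position and covers {s1, s2}; g2 then
beats g3 (score 1 vs −1) and covers {s3, s4}; g3 is appended once no
uncovered samples remain. Phase 2 puts s2 before s1 (only g1 is mutated in
s2, so L = 1 vs 0) and s4 before s3, giving columns (s2, s1, s4, s3) —
g1's and g2's entries each form a single run of length 2. The overall
mutual-exclusivity coverage of this row order is −2 + 1 + 0 = −1 (it can
be negative; higher is better, and it is invariant under column
permutations).

The same operations are available as a library:

```python
from mutexsort import read_matrix, mutex_sort, permute_matrix, overall_me_coverage

bm = read_matrix("demo.tsv")
res = mutex_sort(bm)            # SortResult with row_order / col_order
print(overall_me_coverage(permute_matrix(bm, res)))   # -1
```

Other subcommands: `mutexsort simulate` (random, shuffled-diagonal and
injected-pattern matrices), `mutexsort bench` (method-comparison sweeps
from a YAML config) and `mutexsort rank-pairs` (where known gene pairs,
e.g. synthetic-lethal pairs, land in a row ordering).

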