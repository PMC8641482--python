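# Methods

## Model and assumptions

`scfem` scores, for each cell and each gene set, the null hypothesis that the
cell's expressed genes are an exchangeable draw from the background universe.
Formally, with background size `N`, set size `K`, `n` expressed background
genes in the cell and `k` of them inside the set, the in-set count is
hypergeometric and the reported p-value is the upper tail `P(X ≥ k)` — the
one-sided over-representation tail of Fisher's exact test. The printed
point-mass formula `C(K,k)·C(N−K,n−k)/C(N,n)` is a single term of that tail;
a point mass alone is not a p-value, and over-representation is the question
being asked, so the tail is what the package computes.

The approach deliberately uses only presence/absence. In droplet scRNA-seq a
non-zero count guarantees at least one captured transcript, while a zero
conflates true absence with dropout; the expression *level* is therefore not
trusted, only the binary event. The flip side is a real limitation: two cell
populations expressing the *same* functions through *different* genes at
different levels are indistinguishable in the FEM, which is why FEM is a
complement to, not a replacement for, expression-level analysis.

Key modelling assumptions:

- **Background = union of the collection's genes.** Genes a cell expresses
  that appear in no set are invisible to the test (they enter neither `n` nor
  `k`); this is required for `n ≤ N` and means the collection defines the
  measurable universe. A user-supplied background can be substituted, in
  which case set members are intersected with it.
- **Independence across sets is not assumed** — the per-cell correction
  (Bonferroni over the `m` sets tested, by default) is valid under arbitrary
  dependence. BH and no correction are selectable; the correction is applied
  within each cell, not across the whole cell × set grid, since each cell is
  a separate family of `m` hypotheses.
- **Cells are never dropped.** A cell expressing no background gene gets an
  all-zero FEM row and a logged warning; part of the point of per-cell
  scoring is to keep cells that quality filters would discard.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `correction` | `bonferroni` | per-cell multiple-testing correction (`bh`, `none`) |
| `log_base` | `10` | base of the information-content log; 10 reads as orders of magnitude of significance, `'e'` gives nats |
| `p_floor` | `1e-300` | adjusted p is clamped here before the log, capping GS at 300 (base 10) and keeping it finite |
| `min_set_size` / `max_set_size` | 1 / ∞ | GMT size filter; no filter by default |
| `workers` | 1 | thread count for evaluating distinct (k, n, K) triples; never changes the result |

Gene identifiers are compared case-sensitively after whitespace trimming;
MSigDB symbols are uppercase by convention, and silent case folding could
merge distinct identifiers in other nomenclatures. `--uppercase-genes` opts
into folding when expression data and collection disagree.

## Numerical choices

- Tail probabilities come from the hypergeometric survival function
  (log-space internally), which matches exact rational-arithmetic summation
  to better than 1e-12 relative error in the regimes tested; `k = 0` and
  `K = N` return exactly 1.
- `k`, `n`, `K`, `N` are exact integers throughout; `k = A Bᵀ` is computed in
  sparse integer arithmetic, so the optimization is algebraically identical
  to looping over explicit set intersections (asserted against that naive
  loop in the tests).
- Since `N` and `K` are fixed for a run, p-values are memoized over distinct
  (k, n, K) triples (packed into a single integer key). Worker threads only
  chunk the evaluation of that distinct-triple list, whose content and order
  are independent of the chunking — hence bit-identical results for any
  worker count.
- BH within a row is the standard step-up (sorted p·m/rank, reverse running
  minimum, capped at 1).
- GS is exactly 0 wherever the adjusted p is exactly 1, so "no enrichment"
  is a true zero and the FEM is sparse-friendly.

## Differential functions and cluster purity

`def_markers` tests each set one-vs-rest per cluster with a two-sided
Wilcoxon rank-sum on GS values — the default marker test of the standard
single-cell toolchains, chosen here for the same robustness reasons. Exact
enumeration is used when both groups have ≤ 25 cells and the pooled sample is
tie-free; otherwise the normal approximation with tie correction applies
(FEM columns are heavily tied by construction — memoized p-values repeat —
so the tie-corrected path is the common one). The effect size is the
difference of mean GS between cluster and rest: GS already lives on a −log p
scale, and a fold change is ill-defined at zero. Rows with `|effect| <
min_effect` are dropped before correction — the absolute value keeps the
down-regulated side of each contrast, so swapping two groups negates the
effect and preserves the p-value within one table. Correction is applied
jointly across all tested (set, cluster) rows, BH by default.

`sc_score` reports, per cluster, the share of its modal ground-truth type
(`SC_i = c_i,max / c_i,T`). Ties in the modal type are resolved to the
lexicographically smallest type name so reports are deterministic; the SC
value itself is tie-free. No aggregate is defined; the CLI prints an
unweighted mean clearly marked as an extension.

## Synthetic data

The generator plants cell-type-specific pathway activity in a sparse
Bernoulli presence model: gene `g` is expressed in cell `j` with probability
`signal_rate` if `g` belongs to the planted set matched to `j`'s type, else
`baseline_rate`; expressed entries carry a count of `1 + Poisson(1)` so
binarization is exercised on genuine counts. Defaults — 4 types × 50 cells,
800 genes, 4 disjoint 40-gene sets, baseline 0.05, signal 0.6 — give
dropout-dominated sparsity typical of droplet data with unambiguous planted
structure. Planted sets are disjoint by default for a clean
parameter-recovery surface; an `overlap_fraction` option makes consecutive
sets share a block of genes, emulating the heavy overlap of real MSigDB
collections.

What the generator does **not** emulate: negative-binomial count dispersion,
library-size variation between cells, batch effects, and correlated gene
modules outside the planted sets. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under its own model — that expressed
in-set counts are hypergeometric under the null — not that any particular
biological dataset will cluster perfectly.

## Problem sizes used in the checks

The automated checks run the exactness comparisons on 200 random parameter
tuples with `N ≤ 60` and 20 random pipeline instances up to 50 cells × 100
genes × 15 sets (sizes where rational-arithmetic oracles are instant);
recovery on five seeds of the default design (200 cells, 4 sets); null
calibration on 200 label permutations of a signal-free 40-cell dataset; and
one scale run shaped like a 2,700-cell dataset against a 1,499-set
collection (20 genes per set, baseline 0.02, signal 0.3) to exercise the
memoized path at realistic dimensions.

## Known limitations

- Enrichment depends on the collection: a gene set missing from the GMT can
  never be detected, and background choice shifts every p-value.
- Per-cell Bonferroni is conservative for large collections (m ≈ 10⁴ for GO);
  BH is available but changes the GS scale.
- The rank-sum DEF test treats cells as exchangeable within groups; it does
  not model batch or donor structure.
- No HDF5/loom/h5ad IO; normalization, dimensionality reduction and
  clustering are delegated to existing toolchains — this package consumes
  their cluster labels and produces a matrix they can consume.
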