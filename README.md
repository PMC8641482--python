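# scfem — functional expression matrices for single-cell RNA-seq

`scfem` converts a single-cell **gene expression matrix** (GEM, genes × cells)
into a **functional expression matrix** (FEM, gene sets × cells): each entry
measures how strongly one cell's expressed genes over-represent one gene set
(a pathway, GO term, or signature). Because scRNA-seq data are sparse and
dropout-heavy, presence/absence of a gene is more trustworthy than its
measured level — so instead of rank-based single-sample scores, `scfem` asks
a counting question per cell and per set.

## The statistic

Let *N* be the background universe (the non-redundant union of all genes in
the collection), *K* the size of a gene set, *n* the number of background
genes a cell expresses (any strictly positive value), and *k* the number of
those that fall inside the set. Under the null that expressed genes are
exchangeable with the background, *k* is hypergeometric, and the enrichment
p-value is the one-sided over-representation tail of Fisher's exact test:

```
p = P(X ≥ k),   X ~ Hypergeom(N, K, n),
    P(X = i) = C(K, i) · C(N−K, n−i) / C(N, n)
```

After a per-cell multiple-testing correction (Bonferroni by default, across
the *m* sets tested per cell; BH or none selectable), the p-value becomes
**information content**:

```
GS[cell, set] = −log10(adj_p)
```

The FEM of GS values can stand in for the GEM in downstream tools: cluster
it, embed it, or test **differentially expressed functions (DEF)** between
clusters with a one-vs-rest Wilcoxon rank-sum test. Cluster quality against
known cell types is summarized by the per-cluster purity score
`SC_i = c_i,max / c_i,T` (the modal type's share of cluster *i*).

Computation is vectorized: the binarized cells × genes matrix `A` and the
sets × genes membership matrix `B` give all overlap counts at once as
`k = A Bᵀ`, and since *N* and *K* are constant across cells each distinct
(k, n, K) triple is evaluated only once. A 2,700-cell × 1,499-set run takes
a few seconds on one CPU.

## Worked example

Simulate a dataset with four cell types and four planted 40-gene pathways
(background genes expressed in 5% of cells, planted-pathway genes in 60% of
their matched type), then run the full pipeline:

```sh
fem simulate --types 4 --cells 50 --genes 800 --sets 4 --set-size 40 --seed 1 --out demo
fem compute --expr demo --gmt demo/gene_sets.gmt --out demo/fem.tsv
# -> FEM written to demo/fem.tsv: 200 cells x 4 sets (N=160, zero-n cells=0)

fem score --labels demo/labels.tsv
# cluster  size  modal_type  sc
# type0    50    type0       1
# type1    50    type1       1
# type2    50    type2       1
# type3    50    type3       1
# # mean SC (unweighted, extension): 1

fem def --fem demo/fem.tsv --labels demo/labels.tsv --top 1
# set_name  cluster  effect   statistic  p            adj_p
# SET000    type0    11.7283  7500       5.27365e-44  2.10946e-43
# SET001    type1    10.8385  7500       5.27165e-44  2.10946e-43
# SET002    type2    11.8067  7500       5.27365e-44  2.10946e-43
# SET003    type3    11.4431  7500       5.27298e-44  2.10946e-43
```

Reading the output: `N=160` is the background size (the union of the four
planted sets). Every cluster is pure (`sc = 1`) against the planted types,
and the top differential function of each cluster is exactly its planted
pathway, with an effect of ≈ 11 — the planted set's adjusted enrichment
p-value is about 10⁻¹¹ stronger (in log10 units) inside its matched type
than outside.

The same works on real data: point `--expr` at a 10x-style triplet directory
(`matrix.mtx` + `barcodes.tsv` + `genes.tsv`/`features.tsv.gz`) or a dense
TSV/CSV, and `--gmt` at any MSigDB-dialect GMT collection.

The Python API mirrors the CLI: `read_gmt`, `read_10x_triplet`,
`compute_fem`, `sc_score`, `def_markers`, `top_functions`,
`SyntheticDesign`/`generate`.

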