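"""The FEM algorithm: per-cell hypergeometric gene-set enrichment.

Every expressed gene of a cell is evidence. For cell *j* and gene set *s* the
question is whether the cell's expressed genes over-represent the set relative
to chance. With a background universe of *N* genes (the non-redundant union of
all sets), a set of size *K*, a cell expressing *n* background genes of which
*k* fall in the set, the number of in-set expressed genes under the null is
hypergeometric, and the enrichment p-value is the upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n).

After per-cell multiple-testing correction the p-value is converted to
information content GS = -log(adj_p): the functional expression matrix (FEM),
a cells × sets matrix that can stand in for the gene expression matrix in
downstream clustering and marker analysis.

The heavy lifting is algebraic: with the binary cells × genes matrix A and the
sets × genes membership matrix B, the overlap counts are k = A Bᵀ, and since N
and K are constant across cells the tail probability is evaluated once per
distinct (k, n, K) triple and broadcast back.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import hypergeom

from .expression import ExpressionMatrix
from .genesets import GeneSetCollection, membership_matrix

__all__ = [
    "BinaryExpressionMatrix",
    "OverlapCounts",
    "FEMatrix",
    "binarize",
    "overlap_counts",
    "enrichment_pvalue",
    "adjust_pvalues",
    "information_content",
    "compute_fem",
]

logger = logging.getLogger(__name__)

DEFAULT_P_FLOOR = 1e-300


@dataclass
class BinaryExpressionMatrix:
    """Cells × genes presence/absence matrix.

    ``A[j, g] = 1`` iff gene ``g`` has a strictly positive value in cell
    ``j``. ``n`` counts each cell's expressed genes restricted to the
    background universe (``None`` background means all genes count).
    """

    A: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    n: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.A.shape[0]

    @property
    def n_genes(self) -> int:
        return self.A.shape[1]


@dataclass
class OverlapCounts:
    """Cells × sets intersection sizes plus the test's fixed margins.

    ``k[j, s] = |expressed(j) ∩ members(s)|`` with ``0 <= k <= min(n, K)``.
    """

    k: np.ndarray
    n: np.ndarray
    K: np.ndarray
    N: int
    set_names: tuple[str, ...]
    cell_ids: tuple[str, ...]


@dataclass
class FEMatrix:
    """Cells × sets matrix of enrichment information content GS >= 0."""

    GS: np.ndarray
    set_names: tuple[str, ...]
    cell_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.GS = np.asarray(self.GS, dtype=float)
        if self.GS.shape != (len(self.cell_ids), len(self.set_names)):
            raise ValueError("GS shape does not match cell/set identifier lengths")
        if self.GS.size and self.GS.min() < 0:
            raise ValueError("information content must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.GS.shape[0]

    @property
    def n_sets(self) -> int:
        return self.GS.shape[1]


def binarize(
    expr: ExpressionMatrix, background: Iterable[str] | None = None
) -> BinaryExpressionMatrix:
    """Extract each cell's non-zero expressed genes as a 0/1 matrix.

    Any strictly positive value (count, RPKM, FPKM, ...) marks a gene as
    expressed; the matrix is transposed to cells × genes. ``n`` is computed
    against ``background`` when given.
    """
    A = expr.values.T.tocsr()
    A = sp.csr_matrix(
        (np.ones(A.nnz, dtype=np.int8), A.indices, A.indptr), shape=A.shape
    )
    A.eliminate_zeros()
    if background is None:
        n = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
    else:
        bg = frozenset(background)
        mask = np.fromiter((g in bg for g in expr.gene_ids), dtype=bool, count=len(expr.gene_ids))
        n = np.asarray(A[:, mask].sum(axis=1)).ravel().astype(np.int64)
    return BinaryExpressionMatrix(A, expr.gene_ids, expr.cell_ids, n)


def overlap_counts(
    binary: BinaryExpressionMatrix, collection: GeneSetCollection
) -> OverlapCounts:
    """Count in-set expressed genes per cell via the sparse product A Bᵀ.

    Genes are aligned by identifier; only measured genes inside the background
    enter the product, and ``n`` is recomputed on that restriction so that
    ``n <= N`` always holds.
    """
    bg = collection.background
    mask = np.fromiter(
        (g in bg for g in binary.gene_ids), dtype=bool, count=len(binary.gene_ids)
    )
    if not mask.any():
        raise ValueError(
            "no overlap between measured gene identifiers and the gene-set background"
        )
    genes = list(np.asarray(binary.gene_ids)[mask])
    A = binary.A[:, mask]
    B = membership_matrix(collection, genes)
    k = np.asarray((A @ B.T.astype(np.int64)).todense())
    n = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
    return OverlapCounts(
        k=k,
        n=n,
        K=collection.set_sizes,
        N=collection.n_background,
        set_names=tuple(collection.set_names),
        cell_ids=tuple(binary.cell_ids),
    )


def enrichment_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n).

    The one-sided over-representation tail of Fisher's exact test: the
    probability that at least ``k`` of the cell's ``n`` expressed background
    genes fall in a set of size ``K`` drawn from ``N`` by chance. Evaluated
    through the survival function in log-space, exact to better than twelve
    significant digits for moderate N.
    """
    for name, value in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(value) != value:
            raise ValueError(f"{name} must be an integer, got {value!r}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if N < 1:
        raise ValueError(f"N must be >= 1, got N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"n must satisfy 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"K must satisfy 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k must satisfy 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def _tail_pvalues(
    k: np.ndarray, n: np.ndarray, K: np.ndarray, N: int, workers: int = 1
) -> np.ndarray:
    """Vectorised P(X >= k) with memoisation over distinct (k, n, K) triples.

    N and K are fixed for a run, so distinct triples are typically far fewer
    than cells × sets entries; each is evaluated once. The result is
    bit-identical for any ``workers`` value: the distinct-triple list and its
    ordering do not depend on how the evaluation is chunked.
    """
    k = np.asarray(k, dtype=np.int64)
    nn = np.broadcast_to(np.asarray(n, dtype=np.int64)[:, None], k.shape)
    KK = np.broadcast_to(np.asarray(K, dtype=np.int64)[None, :], k.shape)
    # pack each (k, n, K) triple into one int64 key for fast uniquing
    base = np.int64(N + 1)
    key = (k.ravel() * base + nn.ravel()) * base + KK.ravel()
    uniq, inverse = np.unique(key, return_inverse=True)
    uk = uniq // (base * base)
    un = (uniq // base) % base
    uK = uniq % base

    def eval_chunk(lo: int, hi: int) -> np.ndarray:
        with np.errstate(divide="ignore"):
            p = hypergeom.sf(uk[lo:hi] - 1, N, uK[lo:hi], un[lo:hi])
        return np.clip(p, 0.0, 1.0)

    m = len(uniq)
    if workers <= 1 or m < 1024:
        up = eval_chunk(0, m)
    else:
        bounds = np.linspace(0, m, workers + 1, dtype=int)
        with ThreadPoolExecutor(max_workers=workers) as pool:
            parts = list(
                pool.map(lambda ab: eval_chunk(*ab), zip(bounds[:-1], bounds[1:]))
            )
        up = np.concatenate(parts)
    up[uk == 0] = 1.0
    return up[inverse].reshape(k.shape)


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction applied within each cell (row).

    ``m`` is the number of gene sets tested per cell. ``bonferroni`` is
    ``min(1, m p)``; ``bh`` is the Benjamini–Hochberg step-up within the row;
    ``none`` returns the input unchanged.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() <= 0 or p.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        m = p.shape[-1]
        return np.minimum(1.0, p * m)
    if method == "bh":
        m = p.shape[-1]
        order = np.argsort(p, axis=-1)
        ranked = np.take_along_axis(p, order, axis=-1)
        scaled = ranked * (m / np.arange(1, m + 1))
        adj = np.minimum.accumulate(scaled[..., ::-1], axis=-1)[..., ::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty_like(adj)
        np.put_along_axis(out, order, adj, axis=-1)
        return out
    raise ValueError(f"unknown correction method {method!r}")


def information_content(
    adj_p: np.ndarray,
    log_base: float | str = 10,
    p_floor: float = DEFAULT_P_FLOOR,
) -> np.ndarray:
    """Convert adjusted p-values to information content GS = -log(adj_p).

    Smaller p means stronger, less-random enrichment and hence more
    information. The p-value is clamped at ``p_floor`` before the log so GS
    stays finite; ``log_base`` 10 reads as orders of magnitude of
    significance, ``'e'`` gives nats.
    """
    adj_p = np.asarray(adj_p, dtype=float)
    if adj_p.size and (adj_p.min() <= 0 or adj_p.max() > 1):
        raise ValueError("adjusted p-values must lie in (0, 1]")
    if not 0 < p_floor < 1:
        raise ValueError("p_floor must lie in (0, 1)")
    gs = -np.log(np.maximum(adj_p, p_floor))
    if log_base == "e":
        return gs
    base = float(log_base)
    if base <= 1:
        raise ValueError("log_base must be > 1 or 'e'")
    return gs / math.log(base)


def compute_fem(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    correction: str = "bonferroni",
    log_base: float | str = 10,
    p_floor: float = DEFAULT_P_FLOOR,
    workers: int = 1,
) -> FEMatrix:
    """Convert a gene expression matrix into a functional expression matrix.

    Pipeline: binarize → overlap counts (sparse A Bᵀ) → memoised hypergeometric
    upper-tail p-values → per-cell correction → information content. The
    result does not depend on ``workers``, which only chunks the evaluation of
    distinct (k, n, K) triples.

    Cells expressing no background gene get an all-zero FEM row and a logged
    warning — no cell is ever dropped.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    binary = binarize(expr, collection.background)
    counts = overlap_counts(binary, collection)
    zero_n = int((counts.n == 0).sum())
    if zero_n:
        logger.warning(
            "%d cell(s) express no background gene; their FEM rows are all zero", zero_n
        )
    logger.info(
        "FEM: %d cells, %d sets, background N=%d, %d zero-n cells",
        len(counts.cell_ids), len(counts.set_names), counts.N, zero_n,
    )
    p = _tail_pvalues(counts.k, counts.n, counts.K, counts.N, workers=workers)
    adj = adjust_pvalues(p, method=correction)
    gs = information_content(adj, log_base=log_base, p_floor=p_floor)
    return FEMatrix(
        gs,
        counts.set_names,
        counts.cell_ids,
        metadata={
            "correction": correction,
            "log_base": log_base,
            "p_floor": p_floor,
            "N": counts.N,
            "zero_n_cells": zero_n,
        },
    )
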