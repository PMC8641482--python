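"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.sparse as sp

from scfem import ExpressionMatrix, GeneSetCollection, SyntheticDesign, generate


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) by direct summation of point masses
    C(K, i) C(N-K, n-i) / C(N, n), in rational arithmetic."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


def random_instance(rng, n_cells=30, n_genes=80, n_sets=12, density=0.15,
                    genes_per_set=(3, 12)):
    """A random small expression matrix + gene-set collection for oracle
    comparisons. Returns (ExpressionMatrix, GeneSetCollection)."""
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{j}" for j in range(n_cells)]
    values = (rng.random((n_genes, n_cells)) < density) * (
        1 + rng.poisson(1.0, (n_genes, n_cells))
    )
    expr = ExpressionMatrix(sp.csr_matrix(values), np.array(genes, dtype=object),
                            np.array(cells, dtype=object))
    members = []
    for s in range(n_sets):
        size = rng.integers(genes_per_set[0], genes_per_set[1] + 1)
        members.append(rng.choice(genes, size=size, replace=False))
    coll = GeneSetCollection.from_sets([f"s{s}" for s in range(n_sets)], members)
    return expr, coll


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard planted-signal design: 4 types x 50 cells, 800 genes,
    4 disjoint 40-gene sets, baseline 0.05, signal 0.6."""
    return generate(SyntheticDesign(seed=20260922))


@pytest.fixture(scope="session")
def planted_fem(planted_dataset):
    from scfem import compute_fem

    expr, coll, labels = planted_dataset
    return compute_fem(expr, coll), labels
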