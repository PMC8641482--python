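"""Expression-matrix IO: 10x-style Matrix Market triplets and dense text.

The canonical in-memory orientation is genes × cells, matching how 10x
distributes count matrices. The functional expression matrix (FEM) is written
sets × cells so it can be fed back into standard single-cell toolchains as a
drop-in feature × cell matrix.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_dense",
    "write_dense",
    "write_fem",
    "read_fem",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class ExpressionMatrix:
    """Genes × cells matrix of non-negative counts or normalized expression.

    ``values`` may be any scipy sparse matrix or a dense ndarray; it is stored
    as CSR. Accepts read counts as well as normalized values (RPKM/FPKM) —
    downstream only presence/absence matters.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(list(self.gene_ids), "gene")
        _check_unique(list(self.cell_ids), "cell")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _find_member(directory: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"{directory}: missing {what} file (looked for {', '.join(candidates)})"
    )


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _deduplicate(ids: list[str], what: str) -> list[str]:
    """Disambiguate duplicates by appending .1, .2, ... with a warning."""
    counts: dict[str, int] = {}
    out: list[str] = []
    n_dupes = 0
    for name in ids:
        k = counts.get(name, 0)
        counts[name] = k + 1
        if k == 0:
            out.append(name)
        else:
            n_dupes += 1
            new = f"{name}.{k}"
            while new in counts:
                k += 1
                new = f"{name}.{k}"
            counts[new] = 1
            out.append(new)
    if n_dupes:
        warnings.warn(
            f"{n_dupes} duplicate {what} identifiers disambiguated with numeric suffixes"
        )
    return out


def read_10x_triplet(directory) -> ExpressionMatrix:
    """Read a 10x-style Matrix Market triplet directory.

    Supports the v2 dialect (``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``)
    and the v3 dialect (gzipped, ``features.tsv.gz`` with three columns). When
    the feature file has a second column (gene symbol) it is used as the gene
    identifier, since gene-set collections are keyed by symbol.
    """
    directory = Path(directory)
    mtx = _find_member(directory, ["matrix.mtx", "matrix.mtx.gz"], "matrix")
    feat = _find_member(
        directory,
        ["genes.tsv", "features.tsv", "genes.tsv.gz", "features.tsv.gz"],
        "features/genes",
    )
    bars = _find_member(directory, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes")

    values = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    feat_rows = [line.split("\t") for line in _read_lines(feat)]
    gene_ids = [row[1] if len(row) >= 2 else row[0] for row in feat_rows]
    cell_ids = _read_lines(bars)

    if values.shape[0] != len(gene_ids):
        raise ValueError(
            f"{mtx.name} declares {values.shape[0]} rows but {feat.name} "
            f"lists {len(gene_ids)} features"
        )
    if values.shape[1] != len(cell_ids):
        raise ValueError(
            f"{mtx.name} declares {values.shape[1]} columns but {bars.name} "
            f"lists {len(cell_ids)} barcodes"
        )
    gene_ids = _deduplicate(gene_ids, "feature")
    cell_ids = _deduplicate(cell_ids, "barcode")
    return ExpressionMatrix(values, np.array(gene_ids, dtype=object), np.array(cell_ids, dtype=object))


def write_10x_triplet(expr: ExpressionMatrix, directory) -> None:
    """Write a v2-dialect triplet (matrix.mtx, genes.tsv, barcodes.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(expr.values))
    with open(directory / "genes.tsv", "w", encoding="utf-8") as fh:
        for g in expr.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for b in expr.cell_ids:
            fh.write(f"{b}\n")


def _sep_for(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    return "," if name.endswith(".csv") else "\t"


def read_dense(path, orientation: str = "genes_by_cells") -> ExpressionMatrix:
    """Read a dense delimited matrix (header row + identifier column).

    ``orientation`` names the layout of the *file*; the result is always
    genes × cells. Non-numeric or negative body cells are rejected with their
    row/column coordinates.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy() & ~df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if body.isna().to_numpy().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}")
    neg = np.argwhere(body.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative value {body.iat[i, j]} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if orientation == "cells_by_genes":
        body = body.T
    return ExpressionMatrix(
        sp.csr_matrix(body.to_numpy()),
        body.index.to_numpy(dtype=object),
        body.columns.to_numpy(dtype=object),
    )


def write_dense(expr: ExpressionMatrix, path) -> None:
    """Write genes × cells as delimited text at full float precision."""
    path = Path(path)
    df = pd.DataFrame(
        expr.values.toarray(), index=expr.gene_ids, columns=expr.cell_ids
    )
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_fem(fem, path, format: str = "tsv") -> None:
    """Write a FEM as sets × cells TSV or as a Matrix Market triplet.

    The triplet form (``matrix.mtx`` + ``features.tsv`` holding set names +
    ``barcodes.tsv``) lets standard single-cell toolchains load the FEM as a
    feature × cell matrix in place of a gene expression matrix.
    """
    if format == "tsv":
        df = pd.DataFrame(fem.GS.T, index=fem.set_names, columns=fem.cell_ids)
        df.index.name = "set"
        df.to_csv(Path(path), sep="\t", float_format="%.17g")
    elif format == "mtx_triplet":
        directory = Path(path)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(fem.GS.T))
        with open(directory / "features.tsv", "w", encoding="utf-8") as fh:
            for s in fem.set_names:
                fh.write(f"{s}\n")
        with open(directory / "barcodes.tsv", "w", encoding="utf-8") as fh:
            for b in fem.cell_ids:
                fh.write(f"{b}\n")
    else:
        raise ValueError(f"unknown FEM output format {format!r}")


def read_fem(path, format: str = "tsv"):
    """Read back a FEM written by :func:`write_fem`."""
    from .core import FEMatrix

    if format == "tsv":
        df = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
        return FEMatrix(
            df.to_numpy().T,
            tuple(df.index.astype(str)),
            tuple(df.columns.astype(str)),
        )
    elif format == "mtx_triplet":
        directory = Path(path)
        GS = np.asarray(
            sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx"))).todense()
        )
        set_names = _read_lines(directory / "features.tsv")
        cell_ids = _read_lines(directory / "barcodes.tsv")
        return FEMatrix(GS.T, tuple(set_names), tuple(cell_ids))
    raise ValueError(f"unknown FEM input format {format!r}")
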