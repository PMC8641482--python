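"""Cluster-vs-cell-type agreement: overlap tables and the SC purity score.

For each cluster *i* the SC score is the fraction of the cluster occupied by
its most frequent ground-truth cell type,

    SC_i = c_{i,max} / c_{i,T},

where c_{i,max} is the count of the modal type and c_{i,T} the cluster size.
SC_i = 1 means a pure cluster; low SC flags clusters mixing several types
(which in practice often share a recent developmental origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LabeledCells", "read_labels", "write_labels", "overlap_table", "sc_score"]


@dataclass
class LabeledCells:
    """Per-cell cluster assignment, optionally with ground-truth cell types."""

    cell_ids: np.ndarray
    cluster: np.ndarray
    cell_type: np.ndarray | None = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cluster = np.asarray(self.cluster, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if len(self.cluster) != len(self.cell_ids):
            raise ValueError("cluster labels do not cover all cells")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != len(self.cell_ids):
                raise ValueError("cell_type labels do not cover all cells")

    def __len__(self) -> int:
        return len(self.cell_ids)


def read_labels(path) -> LabeledCells:
    """Read a label TSV with columns cell_id, cluster[, cell_type]."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = {"cell_id", "cluster"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: label file must have columns cell_id, cluster")
    cell_type = df["cell_type"].to_numpy(dtype=object) if "cell_type" in df.columns else None
    return LabeledCells(
        df["cell_id"].to_numpy(dtype=object),
        df["cluster"].to_numpy(dtype=object),
        cell_type,
    )


def write_labels(labels: LabeledCells, path) -> None:
    data = {"cell_id": labels.cell_ids, "cluster": labels.cluster}
    if labels.cell_type is not None:
        data["cell_type"] = labels.cell_type
    pd.DataFrame(data).to_csv(Path(path), sep="\t", index=False)


def overlap_table(labels: LabeledCells) -> pd.DataFrame:
    """Cluster × type contingency table of cell counts."""
    if labels.cell_type is None:
        raise ValueError("overlap_table requires ground-truth cell types")
    table = pd.crosstab(
        pd.Series(labels.cluster, name="cluster"),
        pd.Series(labels.cell_type, name="cell_type"),
    )
    return table


def sc_score(labels: LabeledCells) -> pd.DataFrame:
    """Per-cluster SC purity score with the modal cell type.

    Returns a DataFrame indexed by cluster with columns ``size``,
    ``modal_type`` and ``sc``. When two types tie for the modal count the
    lexicographically smallest type name is reported (the SC value itself is
    unaffected by the tie).
    """
    table = overlap_table(labels)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty cluster in labels")
    sizes = table.sum(axis=1)
    c_max = table.max(axis=1)
    # crosstab sorts type columns, so idxmax's first-hit rule is the
    # lexicographic tie-break
    modal = table.idxmax(axis=1)
    return pd.DataFrame(
        {"size": sizes, "modal_type": modal.astype(str), "sc": c_max / sizes}
    )
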