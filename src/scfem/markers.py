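"""Differentially expressed functions (DEF) between clusters.

Given a FEM and cluster labels (from FEM-based clustering, "FC-DEF", or from
expression-based clustering, "GC-DEF" — the module is agnostic to where the
labels came from), each gene set is tested one-vs-rest per cluster with a
two-sided Wilcoxon rank-sum test on its information-content values. The
effect size is the difference of mean GS between the cluster and the rest:
FEM values already live on a -log p scale, where a log-fold-change would be
ill-defined at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import FEMatrix
from .evaluation import LabeledCells

__all__ = ["def_markers", "top_functions"]

# exact null enumeration is used up to this group size when the pooled
# sample is tie-free; beyond it (or with ties) the normal approximation
# with tie correction applies
EXACT_MAX_GROUP = 25


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value and U statistic for x vs y."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        return float(len(x) * len(y) / 2), 1.0
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def def_markers(
    fem: FEMatrix,
    labels: LabeledCells,
    min_effect: float = 0.0,
    correction: str = "bh",
) -> pd.DataFrame:
    """One-vs-rest rank-sum DEF table over all (set, cluster) pairs.

    Rows with ``|effect| < min_effect`` are dropped before correction;
    correction (BH by default, Bonferroni selectable) is applied jointly
    across all tested rows. The result is sorted by cluster, then adjusted
    p ascending, then effect descending.
    """
    if min_effect < 0:
        raise ValueError("min_effect must be non-negative")
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction method {correction!r}")
    pos = {c: i for i, c in enumerate(labels.cell_ids)}
    try:
        order = np.array([pos[c] for c in fem.cell_ids])
    except KeyError as exc:
        raise ValueError(f"cell {exc.args[0]!r} in FEM has no label") from None
    cluster = np.asarray(labels.cluster, dtype=object)[order]
    uniq, counts = np.unique(cluster.astype(str), return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"cluster {small[0]!r} has fewer than 2 cells")

    rows = []
    for cl in uniq:
        mask = cluster.astype(str) == cl
        in_gs = fem.GS[mask]
        out_gs = fem.GS[~mask]
        effects = in_gs.mean(axis=0) - out_gs.mean(axis=0)
        for s, set_name in enumerate(fem.set_names):
            if abs(effects[s]) < min_effect:
                continue
            stat, p = _rank_sum_test(in_gs[:, s], out_gs[:, s])
            rows.append((set_name, cl, float(effects[s]), stat, p))
    table = pd.DataFrame(
        rows, columns=["set_name", "cluster", "effect", "statistic", "p"]
    )
    if len(table):
        method = "fdr_bh" if correction == "bh" else "bonferroni"
        table["adj_p"] = multipletests(table["p"].to_numpy(), method=method)[1]
        table["adj_p"] = table["adj_p"].clip(upper=1.0)
    else:
        table["adj_p"] = pd.Series(dtype=float)
    table = table.sort_values(
        ["cluster", "adj_p", "effect"], ascending=[True, True, False]
    ).reset_index(drop=True)
    return table


def top_functions(table: pd.DataFrame, per_cluster: int = 5) -> pd.DataFrame:
    """Top up-regulated functions per cluster.

    Keeps positive-effect rows, orders by adjusted p ascending with ties
    broken by effect descending then set name, and returns the first
    ``per_cluster`` rows of each cluster.
    """
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    up = table[table["effect"] > 0]
    up = up.sort_values(
        ["cluster", "adj_p", "effect", "set_name"],
        ascending=[True, True, False, True],
    )
    return up.groupby("cluster", group_keys=False).head(per_cluster).reset_index(drop=True)
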