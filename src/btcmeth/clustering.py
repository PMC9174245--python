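"""Unsupervised hierarchical clustering and clinical association tests.

Samples are clustered on island-level β (or somatic-change) profiles
with Euclidean distance and Ward linkage by default — the standard
choice for methylation heatmaps. Cluster membership is then tested
against dichotomised clinical variables (e.g. stage I–II vs III–IV,
tumour-only clusters vs clusters mixed with normals) by a two-sided
Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "ClusteringResult",
    "uhc",
    "cluster_assoc",
    "collapse_stage",
    "cluster_normal_mix",
    "to_newick",
]


@dataclass
class ClusteringResult:
    linkage: np.ndarray            # scipy linkage matrix, n-1 merges
    labels: pd.Series              # sample id -> cluster label at cut k
    distance: str
    method: str
    k: int

    def newick(self) -> str:
        return to_newick(self.linkage, list(self.labels.index))


def uhc(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    method: str = "ward",
    k: int = 2,
) -> ClusteringResult:
    """Hierarchically cluster samples (rows) and cut at ``k`` clusters.

    Missing values are imputed with the column (island) mean first.
    Deterministic given the input.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two samples")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} samples")
    filled = matrix.apply(lambda col: col.fillna(col.mean()), axis=0)
    if filled.isna().any().any():
        raise ValueError("columns with no observed values cannot be imputed")
    Z = hierarchy.linkage(filled.to_numpy(), method=method, metric=distance)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(
        linkage=Z,
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        distance=distance,
        method=method,
        k=k,
    )


def collapse_stage(stage: pd.Series) -> pd.Series:
    """Dichotomise tumour stage: I–II (early) vs III–IV (late)."""
    mapping = {"I": "I-II", "II": "I-II", "III": "III-IV", "IV": "III-IV"}
    return stage.map(mapping)


def cluster_normal_mix(labels: pd.Series, sheet: pd.DataFrame) -> pd.Series:
    """Dichotomise clusters: contains normals ('mixed') vs tumour-only.

    Returned only for tumour samples, ready to cross with a clinical
    dichotomy.
    """
    groups = sheet.loc[labels.index, "group"]
    with_normals = set(labels[groups == "normal"].unique())
    tumours = labels.index[groups == "tumour"]
    return pd.Series(
        np.where(labels.loc[tumours].isin(with_normals), "mixed",
                 "tumour-only"),
        index=tumours,
        name="cluster_type",
    )


def cluster_assoc(labels: pd.Series, clinical: pd.Series) -> tuple[pd.DataFrame, float]:
    """Two-sided Fisher exact test of a 2×2 cluster × clinical table.

    Both inputs must be two-valued after any collapsing; samples with a
    missing clinical value are dropped. A zero margin is an error.
    """
    df = pd.concat([labels, clinical], axis=1, join="inner").dropna()
    if df.empty:
        raise ValueError("no overlapping samples with observed values")
    table = pd.crosstab(df.iloc[:, 0], df.iloc[:, 1])
    if table.shape != (2, 2):
        raise ValueError(
            f"need a 2x2 table after collapsing, got shape {table.shape}"
        )
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the contingency table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return table, float(p)


def to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
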