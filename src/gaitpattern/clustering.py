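"""K-means cluster structure of the trial matrix, silhouette model selection,
distance matrix, agglomerative merge tree and loading-rate tables.

The standardized trial matrix is clustered with K-means (squared Euclidean
objective, greedy spread-out seeding, best of ``restarts`` runs by inertia).
The number of clusters is chosen by scanning candidate K and keeping the one
with the highest mean silhouette.  "Loading rates" summarize how a grouping
of the rows (by subject, by condition, or by subject x condition x side)
distributes over the clusters: for each group, the fraction of its trials in
each cluster; a group entirely inside one cluster has maximum rate 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .errors import ParameterError
from .waveform_prep import FeatureMatrix

Grouping = Literal["subject", "condition", "subject_condition_side"]


def _as_array(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ParameterError("matrix must be 2-D")
    return X


@dataclass
class ClusterResult:
    """One K-means solution. ``assignments`` uses 1-based cluster ids 1..k."""

    k: int
    assignments: np.ndarray
    silhouette_per_row: np.ndarray
    mean_silhouette: float
    inertia: float
    seed: int
    restarts: int


def kmeans_cluster(
    matrix: FeatureMatrix | np.ndarray, k: int, seed: int = 0, restarts: int = 25
) -> ClusterResult:
    """Best-of-restarts K-means with the squared-Euclidean objective."""
    X = _as_array(matrix)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ParameterError(f"k must be in [2, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    assignments = km.labels_ + 1
    sil, mean_sil = silhouette_values(X, assignments)
    return ClusterResult(
        k=k,
        assignments=assignments,
        silhouette_per_row=sil,
        mean_silhouette=mean_sil,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def silhouette_values(
    matrix: FeatureMatrix | np.ndarray, assignments: Sequence[int] | np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-row silhouette (Euclidean) and its mean.

    A clustering where every cluster is a singleton (or with fewer than two
    clusters) has no defined between/within contrast; those rows get
    silhouette 0 by convention, with a warning.
    """
    X = _as_array(matrix)
    labels = np.asarray(assignments)
    if labels.size != X.shape[0]:
        raise ParameterError("assignments do not align with matrix rows")
    n_labels = np.unique(labels).size
    if n_labels < 2 or n_labels >= X.shape[0]:
        warnings.warn(
            "silhouette undefined (every cluster a singleton or a single cluster); "
            "returning 0 per row",
            stacklevel=2,
        )
        sil = np.zeros(X.shape[0])
        return sil, 0.0
    sil = silhouette_samples(X, labels)
    return sil, float(sil.mean())


def select_k(
    matrix: FeatureMatrix | np.ndarray,
    k_candidates: Sequence[int],
    seed: int = 0,
    restarts: int = 25,
) -> tuple[int, dict[int, float]]:
    """Choose K by maximum mean silhouette; ties go to the smaller K."""
    X = _as_array(matrix)
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ParameterError("k_candidates is empty")
    if candidates[0] < 2 or candidates[-1] > X.shape[0]:
        raise ParameterError(
            f"k candidates must lie in [2, {X.shape[0]}], got {candidates[0]}..{candidates[-1]}"
        )
    scores: dict[int, float] = {}
    for k in candidates:
        scores[k] = kmeans_cluster(X, k, seed=seed, restarts=restarts).mean_silhouette
    best_k = max(candidates, key=lambda k: (scores[k], -k))
    if scores[best_k] <= 0.5:  # Rousseeuw's band: <= 0.5 is weak/artificial structure
        warnings.warn(
            f"weak cluster structure: best mean silhouette {scores[best_k]:.3f} at k={best_k}",
            stacklevel=2,
        )
    return best_k, scores


def distance_matrix(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean trial-by-trial distance matrix (zero diagonal)."""
    X = _as_array(matrix)
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean"))


@dataclass
class MergeTree:
    """Agglomerative merge sequence (scipy linkage encoding) plus exports."""

    linkage_matrix: np.ndarray
    linkage_rule: str
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.linkage_matrix)

    def to_nested(self) -> list:
        """Nested [left, right, height] lists; leaves are integer row indices."""
        nodes: dict[int, object] = {i: i for i in range(self.n_leaves)}
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            nodes[self.n_leaves + step] = [nodes[int(a)], nodes[int(b)], float(h)]
        return nodes[self.n_leaves + len(self.linkage_matrix) - 1]

    def to_newick(self) -> str:
        """Newick text with merge heights as internal-node branch support."""

        def render(node) -> str:
            if isinstance(node, (int, np.integer)):
                return f"row{int(node)}"
            left, right, h = node
            return f"({render(left)},{render(right)}):{h:.6g}"

        return render(self.to_nested()) + ";"


def merge_tree(
    matrix: FeatureMatrix | np.ndarray, linkage_rule: str = "ward"
) -> MergeTree:
    """Full agglomerative merge tree (default Ward on Euclidean distances).

    Ward is the default because its variance objective matches K-means;
    any scipy linkage rule name is accepted.
    """
    X = _as_array(matrix)
    if X.shape[0] < 2:
        raise ParameterError("merge_tree needs at least 2 rows")
    Z = linkage(X, method=linkage_rule, metric="euclidean")
    return MergeTree(Z, linkage_rule, X.shape[0])


@dataclass
class LoadingRateTable:
    """Per-group distribution over clusters.

    ``rates`` is a groups x clusters table whose rows sum to 1; ``max_rate``
    is each group's largest share.  ``summary`` reports the number of groups,
    how many sit entirely in one cluster, and the median of the max rates.
    """

    grouping: Grouping
    rates: pd.DataFrame
    max_rate: pd.Series
    summary: dict

    @property
    def n_groups_at_one(self) -> int:
        return int(self.summary["n_groups_at_one"])


def loading_rates(
    assignments: Sequence[int] | np.ndarray,
    row_labels: pd.DataFrame,
    grouping: Grouping,
) -> LoadingRateTable:
    """Fraction of each group's trials falling in every cluster."""
    labels = np.asarray(assignments)
    if len(row_labels) != labels.size:
        raise ParameterError("row labels do not align with assignments")
    if grouping == "subject":
        keys = row_labels["subject"].astype(str)
    elif grouping == "condition":
        keys = row_labels["condition"].astype(str)
    elif grouping == "subject_condition_side":
        keys = (
            row_labels["subject"].astype(str)
            + "|"
            + row_labels["condition"].astype(str)
            + "|"
            + row_labels["side"].astype(str)
        )
    else:
        raise ParameterError(f"unknown grouping {grouping!r}")
    counts = pd.crosstab(keys, pd.Series(labels, index=keys.index, name="cluster"))
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"excluding empty group(s): {list(counts.index[empty])}", stacklevel=2)
        counts = counts[~empty]
    rates = counts.div(counts.sum(axis=1), axis=0)
    max_rate = rates.max(axis=1)
    summary = {
        "n_groups": int(len(rates)),
        "n_groups_at_one": int((max_rate >= 1.0 - 1e-12).sum()),
        "median_max_rate": float(max_rate.median()),
        "max_max_rate": float(max_rate.max()),
    }
    return LoadingRateTable(grouping=grouping, rates=rates, max_rate=max_rate, summary=summary)
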