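"""Clustering evaluation: Hungarian-matched accuracy, ARI, silhouette, RMSE."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "contingency_table",
    "hungarian_accuracy",
    "adjusted_rand_index",
    "silhouette",
    "rmse_cluster_count",
]


def contingency_table(predicted, truth) -> pd.DataFrame:
    """Cluster x type contingency table (rows: predicted, columns: truth)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    return pd.crosstab(pd.Series(predicted, name="cluster"), pd.Series(truth, name="type"))


def hungarian_accuracy(predicted, truth) -> float:
    """Accuracy after optimally matching clusters to types.

    The contingency table is solved as a (zero-padded, hence injective)
    linear assignment problem; each cluster is matched to at most one
    type and unmatched clusters contribute no correct cells.
    """
    table = contingency_table(predicted, truth).to_numpy()
    r, c = linear_sum_assignment(table, maximize=True)
    return float(table[r, c].sum() / table.sum())


def adjusted_rand_index(predicted, truth) -> float:
    """Pair-counting Rand index adjusted for chance.

    The degenerate case where both partitions are constant (expected index
    equals the index) returns 1.0 by the usual convention.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size < 2:
        raise ValueError("need >= 2 cells with matching predicted/truth lengths")
    return float(adjusted_rand_score(truth, predicted))


def silhouette(vectors: np.ndarray, labels) -> float:
    """Mean silhouette coefficient ``(b - a)/max(a, b)`` (Euclidean).

    Conventions: a singleton cluster has a = 0, hence score 1 at any
    positive separation; a cell with a = b = 0 scores 0.
    """
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(X, X)
    scores = np.empty(len(X))
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    for i in range(len(X)):
        own = members[labels[i]]
        a = D[i, own[own != i]].mean() if len(own) > 1 else 0.0
        b = min(D[i, members[u]].mean() for u in uniq if u != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def rmse_cluster_count(estimates, truths) -> float:
    """Root-mean-square error between estimated and true cluster counts."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape or estimates.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    return float(np.sqrt(np.mean((estimates - truths) ** 2)))
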