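"""k-nearest-neighbor decoding of experience labels, evaluated leave-one-out.

The decoder is deliberately minimal: k-NN (default k=1) in Euclidean
feature space, with no feature standardization by default.  Determinism
is guaranteed by explicit tie-breaking — equal distances resolve to the
lowest training-row index (a stable argsort), and for k>1 a tied
majority vote resolves to the label of the nearest tied-class member.

Evaluation is leave-one-out: each mouse is classified from all the
others, and performance is summarized in a confusion matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import schema as S
from .errors import FeatureError
from .normalization import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "knn_predict",
    "loo_predict",
    "loo_evaluate",
    "collapse_features",
    "pairwise_sq_distances",
    "nearest_neighbor_index",
]


@dataclass
class ConfusionMatrix:
    """Counts of actual (rows) versus predicted (columns) classes."""

    classes: list
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def recall(self) -> pd.Series:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            r = np.where(row > 0, np.diag(self.counts) / row, np.nan)
        return pd.Series(r, index=self.classes, name="recall")

    @property
    def precision(self) -> pd.Series:
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(col > 0, np.diag(self.counts) / col, np.nan)
        return pd.Series(p, index=self.classes, name="precision")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @classmethod
    def from_predictions(cls, actual, predicted) -> "ConfusionMatrix":
        classes = sorted(set(actual))
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, p in zip(actual, predicted):
            counts[idx[a], idx.get(p, -1)] += 1
        return cls(classes=classes, counts=counts)


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances, computed stably."""
    diff = X[:, None, :] - X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def knn_predict(train_X, train_y, query, k: int = 1):
    """Classify one query vector by majority vote among its k nearest rows.

    Distance ties resolve to the lowest training-row index; vote ties
    resolve to the label of the nearest member of a tied class.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    query = np.asarray(query, dtype=float).ravel()
    if train_X.ndim != 2 or len(train_X) == 0:
        raise FeatureError("training set must be a nonempty 2-D array")
    if query.shape[0] != train_X.shape[1]:
        raise FeatureError(
            f"query dimension {query.shape[0]} != training dimension {train_X.shape[1]}"
        )
    if not 1 <= k <= len(train_X):
        raise FeatureError(f"k={k} outside [1, n_train={len(train_X)}]")
    d = np.einsum("ij,ij->i", train_X - query, train_X - query)
    order = np.argsort(d, kind="stable")[:k]
    return _vote(train_y[order])


def _vote(neighbor_labels: np.ndarray):
    """Majority vote; ties go to the class whose member appears first
    (i.e. is nearest, since labels arrive sorted by distance)."""
    votes = Counter(neighbor_labels.tolist())
    top = max(votes.values())
    tied = {c for c, v in votes.items() if v == top}
    for lab in neighbor_labels:
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def nearest_neighbor_index(X: np.ndarray) -> np.ndarray:
    """Leave-one-out nearest neighbor of each row (self excluded).

    Label-independent, which makes label-permutation testing with k=1 a
    pure relabeling of a fixed neighbor structure.
    """
    d = pairwise_sq_distances(np.asarray(X, dtype=float))
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)  # argmin takes the lowest index on ties


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each feature column (constant columns are left at 0)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


def loo_predict(X, y, k: int = 1, standardize: bool = False) -> np.ndarray:
    """Leave-one-out k-NN predictions for every row.

    ``standardize`` z-scores the features first (off by default; the
    raw fold scale is the primary analysis, z-scoring is a sensitivity
    check).
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        X = standardize_features(X)
    y = np.asarray(y)
    n = len(X)
    if n < 2:
        raise FeatureError("leave-one-out needs at least 2 samples")
    if not 1 <= k <= n - 1:
        raise FeatureError(f"k={k} outside [1, n-1={n - 1}]")
    if k == 1:
        return y[nearest_neighbor_index(X)]
    d = pairwise_sq_distances(X)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return np.array([_vote(y[row]) for row in order])


def loo_evaluate(data: FeatureMatrix, k: int = 1, standardize: bool = False) -> ConfusionMatrix:
    """Leave-one-out evaluation of the k-NN decoder on a feature matrix."""
    pred = loo_predict(data.X, data.y, k=k, standardize=standardize)
    return ConfusionMatrix.from_predictions(data.y, pred)


def collapse_features(data: FeatureMatrix, by: str):
    """Reduce the feature space to probe where the decoding signal lives.

    ``by="gene"`` / ``by="structure"`` — one sub-matrix per gene (its
    values across structures) or per structure (its genes); returns a
    dict name -> FeatureMatrix.  ``by="mean_over_structures"`` — average
    each gene over structures (losing spatial information); returns one
    FeatureMatrix with a column per gene.
    """
    parsed = [S.split_feature(c) for c in data.values.columns]
    genes = list(dict.fromkeys(g for g, _ in parsed))
    structures = list(dict.fromkeys(s for _, s in parsed))
    if by == "gene":
        return {
            g: data.select([c for c, (gg, _) in zip(data.values.columns, parsed) if gg == g])
            for g in genes
        }
    if by == "structure":
        return {
            s: data.select([c for c, (_, ss) in zip(data.values.columns, parsed) if ss == s])
            for s in structures
        }
    if by == "mean_over_structures":
        means = pd.DataFrame(
            {
                g: data.values[
                    [c for c, (gg, _) in zip(data.values.columns, parsed) if gg == g]
                ].mean(axis=1)
                for g in genes
            }
        )
        return replace(data, values=means)
    raise FeatureError(f"unknown collapse mode: {by!r}")
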