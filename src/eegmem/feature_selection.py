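"""ROC-separability feature scoring and top-k filter selection.

Each feature is scored by how well it separates the two classes on its own:
the Mann-Whitney ROC area of the feature used as a ranker, folded about
chance, ``score = |AUC - 0.5|``.  The score is 0 when the two
class-conditional distributions coincide and 0.5 when they are completely
separated (every value of one class beyond every value of the other, in
either direction), and it is invariant under strictly monotone transforms
of the feature and under swapping the class labels.  Ties are credited 0.5,
the standard mid-rank convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class FeatureScore:
    feature_index: int
    score: float


def roc_separability(values_class0, values_class1) -> float:
    """|AUC - 0.5| of one feature as a ranker of class 1 vs class 0."""
    v0 = np.asarray(values_class0, dtype=float).ravel()
    v1 = np.asarray(values_class1, dtype=float).ravel()
    if v0.size == 0 or v1.size == 0:
        raise InputError("both classes need at least one value")
    ranks = rankdata(np.concatenate([v0, v1]))
    r1 = ranks[v0.size :].sum()
    auc = (r1 - v1.size * (v1.size + 1) / 2) / (v0.size * v1.size)
    return abs(auc - 0.5)


def score_features(features: np.ndarray, labels) -> np.ndarray:
    """ROC-separability score of every column of an (n, p) feature matrix."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise InputError("features must be (n_samples, n_features) matching labels")
    is1 = y == 1
    n0, n1 = int((~is1).sum()), int(is1.sum())
    if n0 == 0 or n1 == 0:
        raise InputError("training set must contain both classes")
    ranks = rankdata(x, axis=0)
    r1 = ranks[is1].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2) / (n0 * n1)
    return np.abs(auc - 0.5)


def select_top_features(features: np.ndarray, labels, k: int) -> np.ndarray:
    """Indices of the k highest-scoring features, best first.

    Ties are broken toward the lower feature index, so the selection is
    deterministic and independent of sample order.
    """
    scores = score_features(features, labels)
    p = scores.size
    if not 1 <= k <= p:
        raise ParameterError(f"k must be in [1, {p}]")
    order = np.lexsort((np.arange(p), -scores))
    return order[:k]


class ROCFeatureSelector:
    """Minimal sklearn-style transformer wrapping :func:`select_top_features`.

    ``k`` is capped at the number of available features at fit time, so the
    same configuration can be reused across feature-space sizes.
    """

    def __init__(self, k: int = 500):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.indices_ = select_top_features(X, y, min(self.k, X.shape[1]))
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.indices_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
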