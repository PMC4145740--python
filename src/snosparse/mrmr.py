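"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

mRMR orders features by trading the mutual information each feature shares
with the class label (relevance) against the mean mutual information it
shares with the features already selected (redundancy).  The greedy
first-order scheme is used: step 1 picks the most relevant feature, and
step t picks

    argmax_j  MI(X_j, Y) - (1/|S|) * sum_{X_i in S} MI(X_j, X_i)

over the features j not yet in the selected set S.  Mutual information is
the plug-in estimate from the joint empirical distribution, in nats;
continuous features are discretized first (3 equal-width bins by default,
while low-cardinality features such as one-hot indicators pass through
unchanged).  Ties are broken toward the lower feature index so rankings
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous features are binned before mutual information."""

    n_bins: int = 3
    strategy: str = "width"  # "width" (equal-width) or "frequency"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.strategy not in ("width", "frequency"):
            raise ValueError(f"unknown discretization strategy {self.strategy!r}")


@dataclass
class RankedFeatures:
    """An mRMR-ordered permutation of feature indices with step scores.

    ``scores[t]`` is the greedy objective value of the feature chosen at
    step t (for t = 0 this is its relevance alone).
    """

    order: np.ndarray
    scores: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores must have equal length")
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of feature indices")


def _codes(x: np.ndarray) -> np.ndarray:
    """Map arbitrary discrete values to consecutive integer codes."""
    _, inverse = np.unique(x, return_inverse=True)
    return inverse


def discretize_column(
    x: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()
) -> np.ndarray:
    """Integer-code one feature column for MI estimation.

    Columns with at most ``n_bins`` distinct values (binary flags, one-hot
    indicators) keep their levels; denser columns are binned.
    """
    x = np.asarray(x, dtype=float)
    uniques = np.unique(x)
    if uniques.size <= spec.n_bins:
        return _codes(x)
    if spec.strategy == "width":
        lo, hi = x.min(), x.max()
        edges = np.linspace(lo, hi, spec.n_bins + 1)[1:-1]
    else:
        quantiles = np.linspace(0, 1, spec.n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(x, quantiles))
    return np.digitize(x, edges)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in nats.

    Empirical joint and marginal frequencies are substituted into
    ``sum p(x,y) log[p(x,y) / (p(x) p(y))]``; empty cells contribute zero.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("mutual information needs at least 2 samples")
    xc, yc = _codes(x), _codes(y)
    nx, ny = xc.max() + 1, yc.max() + 1
    joint = np.bincount(xc * ny + yc, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nonzero = joint > 0
    return float(np.sum(joint[nonzero] * np.log(joint[nonzero] / (px @ py)[nonzero])))


_TIE_TOL = 1e-9


def _argmax_lowest_index(values: np.ndarray, tol: float = _TIE_TOL) -> int:
    """Index of the maximum; near-ties (within ``tol``) go to the lowest index.

    Plug-in MI values of distinct contingency tables differ by far more
    than ``tol``; the tolerance only absorbs float noise between
    mathematically equal scores computed along different paths.
    """
    best = np.max(values)
    return int(np.flatnonzero(values >= best - tol)[0])


def _mi_coded(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nonzero = joint > 0
    return float(np.sum(joint[nonzero] * np.log(joint[nonzero] / (px @ py)[nonzero])))


def mrmr_rank(
    X: np.ndarray,
    y: np.ndarray,
    spec: DiscretizationSpec = DiscretizationSpec(),
    names: list[str] | None = None,
) -> RankedFeatures:
    """Rank all feature columns by the greedy first-order mRMR objective."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 features")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of samples")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; relevance is undefined")

    n, p = X.shape
    codes = np.empty((n, p), dtype=np.int64)
    levels = np.empty(p, dtype=np.int64)
    for j in range(p):
        codes[:, j] = discretize_column(X[:, j], spec)
        levels[j] = codes[:, j].max() + 1
    yc = _codes(y)
    ny = yc.max() + 1

    relevance = np.array([_mi_coded(codes[:, j], yc, levels[j], ny) for j in range(p)])
    remaining = np.ones(p, dtype=bool)
    redundancy_sum = np.zeros(p)
    order: list[int] = []
    scores: list[float] = []

    first = _argmax_lowest_index(relevance)
    order.append(first)
    scores.append(float(relevance[first]))
    remaining[first] = False

    while remaining.any():
        last = order[-1]
        for j in np.flatnonzero(remaining):
            redundancy_sum[j] += _mi_coded(
                codes[:, j], codes[:, last], levels[j], levels[last]
            )
        objective = relevance - redundancy_sum / len(order)
        objective[~remaining] = -np.inf
        pick = _argmax_lowest_index(objective)
        order.append(pick)
        scores.append(float(objective[pick]))
        remaining[pick] = False

    return RankedFeatures(order=np.array(order), scores=np.array(scores), names=names)


class MRMRRanker(TransformerMixin, BaseEstimator):
    """Feature ranking/selection transformer built on greedy mRMR.

    Parameters
    ----------
    n_features : int or None
        How many top-ranked features ``transform`` keeps (all if None).
    n_bins, strategy
        Discretization applied to continuous columns before MI estimation.

    Attributes
    ----------
    ranking_ : ndarray
        Feature indices in mRMR order (best first).
    scores_ : ndarray
        Greedy objective value at each selection step.
    """

    def __init__(
        self,
        n_features: int | None = None,
        n_bins: int = 3,
        strategy: str = "width",
    ):
        self.n_features = n_features
        self.n_bins = n_bins
        self.strategy = strategy

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        spec = DiscretizationSpec(n_bins=self.n_bins, strategy=self.strategy)
        ranked = mrmr_rank(X, y, spec=spec)
        self.ranking_ = ranked.order
        self.scores_ = ranked.scores
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        keep = self.ranking_ if self.n_features is None else self.ranking_[: self.n_features]
        return X[:, keep]

    def ranked(self, names: list[str] | None = None) -> RankedFeatures:
        check_is_fitted(self)
        return RankedFeatures(order=self.ranking_, scores=self.scores_, names=names)
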