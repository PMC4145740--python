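"""Evaluation metrics, cross-validation, and incremental feature selection.

Performance on imbalanced site data is summarised by sensitivity (SN),
specificity (SP), accuracy (ACC) and the Matthews correlation coefficient

    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

with MCC defined as 0 whenever a factor of the denominator vanishes.  MCC
is the selection criterion throughout because it stays informative under
the roughly 1:2 positive:negative skew of cysteine-site data.

Incremental feature selection (IFS) evaluates nested prefixes of an
mRMR-ranked feature list: for each prefix size the classifier is scored by
stratified k-fold cross-validation (out-of-fold predictions pooled into a
single confusion matrix), and the prefix with the best MCC wins, smallest
size on ties.  The same fold partition is reused at every size so the
curve isolates the effect of the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, MetaEstimatorMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .mrmr import DiscretizationSpec, RankedFeatures, mrmr_rank


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    """SN/SP/ACC/MCC derived from confusion counts."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_true = y_true == positive
    pos_pred = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


def metrics(counts: ConfusionCounts) -> EvalReport:
    """SN, SP, ACC and MCC from confusion counts.

    Undefined ratios (empty class) are reported as 0, as is MCC when any
    factor of its denominator is zero.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total if counts.total else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / sqrt(denom) if denom else 0.0
    return EvalReport(counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc)


def stratified_kfold(y: np.ndarray, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Seed-deterministic stratified fold assignment.

    Returns an integer array giving each sample's fold; per class, fold
    sizes differ by at most one.
    """
    y = np.asarray(y).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        smallest = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {smallest} has {counts.min()} samples, fewer than "
            f"{n_folds} folds"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    n_folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> EvalReport:
    """Pooled out-of-fold evaluation of a classifier.

    Out-of-fold predictions from all folds are pooled into one confusion
    matrix before computing metrics; with few positives per fold this is
    far more stable than averaging per-fold MCC values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if fold_assignment is None:
        fold_assignment = stratified_kfold(y, n_folds=n_folds, seed=seed)
    predictions = np.empty_like(y)
    for fold in np.unique(fold_assignment):
        test_mask = fold_assignment == fold
        model = clone(estimator)
        model.fit(X[~test_mask], y[~test_mask])
        predictions[test_mask] = model.predict(X[test_mask])
    return metrics(confusion_counts(y, predictions))


@dataclass
class IFSCurve:
    """MCC-vs-prefix-size curve from incremental feature selection."""

    sizes: np.ndarray
    reports: list[EvalReport]
    optimal_size: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "SN": [r.sn for r in self.reports],
                "SP": [r.sp for r in self.reports],
                "ACC": [r.acc for r in self.reports],
                "MCC": [r.mcc for r in self.reports],
            }
        )

    def report_at(self, size: int) -> EvalReport:
        where = np.flatnonzero(self.sizes == size)
        if where.size == 0:
            raise KeyError(f"no IFS evaluation at size {size}")
        return self.reports[int(where[0])]


def ifs(
    X: np.ndarray,
    y: np.ndarray,
    ranking: RankedFeatures | np.ndarray,
    estimator: BaseEstimator,
    n_folds: int = 10,
    step: int = 1,
    seed: int = 0,
) -> IFSCurve:
    """Evaluate nested prefixes of a ranked feature list.

    Prefix sizes run step, 2*step, ... up to the full feature count (which
    is always included); every prefix is scored with
    :func:`cross_validate` on the same fold partition.  The optimal size
    is the MCC argmax, smallest size on ties.
    """
    if step < 1:
        raise ValueError("step must be at least 1")
    order = ranking.order if isinstance(ranking, RankedFeatures) else np.asarray(ranking)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if sorted(order.tolist()) != list(range(p)):
        raise ValueError("ranking must cover every feature column exactly once")

    sizes = list(range(step, p + 1, step))
    if not sizes or sizes[-1] != p:
        sizes.append(p)
    folds = stratified_kfold(y, n_folds=n_folds, seed=seed)

    reports = []
    for size in sizes:
        subset = X[:, order[:size]]
        reports.append(
            cross_validate(subset, y, estimator, fold_assignment=folds)
        )
    mccs = np.array([r.mcc for r in reports])
    optimal = int(np.array(sizes)[int(np.argmax(mccs))])  # argmax -> smallest on ties
    return IFSCurve(sizes=np.array(sizes), reports=reports, optimal_size=optimal)


class IncrementalFeatureSelector(MetaEstimatorMixin, TransformerMixin, BaseEstimator):
    """Transformer that keeps the MCC-optimal prefix of an mRMR ranking.

    If ``ranking`` is None the mRMR order is computed on the fit data;
    otherwise a precomputed permutation of feature indices is used.  After
    ``fit``, ``curve_`` holds the full size-vs-metrics curve, ``ranking_``
    the feature order, and ``n_features_`` the selected prefix length.
    """

    def __init__(
        self,
        estimator: BaseEstimator,
        ranking: np.ndarray | None = None,
        cv: int = 10,
        step: int = 1,
        n_bins: int = 3,
        random_state: int = 0,
    ):
        self.estimator = estimator
        self.ranking = ranking
        self.cv = cv
        self.step = step
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.ranking is None:
            ranked = mrmr_rank(X, y, spec=DiscretizationSpec(n_bins=self.n_bins))
            order = ranked.order
        else:
            order = np.asarray(self.ranking, dtype=int)
        self.curve_ = ifs(
            X,
            y,
            order,
            self.estimator,
            n_folds=self.cv,
            step=self.step,
            seed=self.random_state,
        )
        self.ranking_ = order
        self.n_features_ = self.curve_.optimal_size
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[order[: self.n_features_]] = True
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X[:, self.ranking_[: self.n_features_]]
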