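"""Sparse representation classification, plain and kernelized.

A sparse representation classifier (SRC) treats the training samples as a
dictionary: a test vector y is approximated as a sparse linear combination
of training columns found by orthogonal matching pursuit (OMP), and the
predicted class is the one whose columns alone reconstruct y with the
smallest l2 residual,

    class(y) = argmin_k || y - X alpha_k ||_2,

where alpha_k keeps only the coefficients of class k's columns.

The kernelized variant (KSRC) lifts both the dictionary and the test point
through a kernel.  Because only inner products appear after multiplying the
representation equation by the mapped dictionary, the sparse problem can be
solved entirely in the Gram-matrix linear system: OMP runs with the n x n
kernel matrix K as the dictionary and the kernel column k(X, y) as the
target, and per-class residuals are measured in that same system.  The
Laplacian kernel exp(-||x - y|| / delta) is the default lift; with
``delta="median"`` the bandwidth is set to the median pairwise training
distance at fit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted, validate_data

_DIST_METRICS = {"l2": "euclidean", "l1": "manhattan"}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel used to lift samples before sparse coding.

    ``kind="linear"`` gives plain inner products; ``kind="laplacian"``
    gives exp(-dist(x, y)/delta) with ``metric`` choosing the l2 (default)
    or l1 distance.
    """

    kind: str = "laplacian"
    delta: float = 100.0
    metric: str = "l2"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "laplacian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "laplacian" and not self.delta > 0:
            raise ValueError("laplacian bandwidth delta must be positive")
        if self.metric not in _DIST_METRICS:
            raise ValueError(f"unknown distance metric {self.metric!r}")


@dataclass
class SparseSolution:
    """Result of one OMP run.

    ``alpha`` is zero outside ``support``; ``residual_norms`` records the
    l2 residual after each projection step (index 0 is ||b||).
    """

    alpha: np.ndarray
    support: np.ndarray
    residual_norm: float
    residual_norms: list[float] = field(default_factory=list)


def omp(A: np.ndarray, b: np.ndarray, k: int, eps: float = 1e-6) -> SparseSolution:
    """Orthogonal matching pursuit with at most ``k`` atoms.

    Each iteration selects the unselected column with the largest absolute
    inner product with the current residual (ties -> lowest index),
    re-projects ``b`` onto all selected columns by least squares, and
    updates the residual.  Iteration stops after ``k`` atoms, when the
    residual norm drops to ``eps``, or when the residual is orthogonal to
    every remaining column.  A column that would make the selected set
    rank-deficient is dropped with a warning and never reconsidered.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != b.shape[0]:
        raise ValueError("A must be 2-D with rows matching b")
    if k < 1:
        raise ValueError("sparsity budget k must be at least 1")

    n = A.shape[1]
    support: list[int] = []
    dropped = np.zeros(n, dtype=bool)
    coef = np.empty(0)
    residual = b.copy()
    norms = [float(np.linalg.norm(residual))]
    scale = max(norms[0], 1.0)

    while len(support) < k and not dropped.all():
        corr = np.abs(A.T @ residual)
        corr[dropped] = -np.inf
        if support:
            corr[support] = -np.inf
        pick = int(np.argmax(corr))
        if corr[pick] <= 1e-12 * scale:
            break  # residual orthogonal to every remaining column
        trial = support + [pick]
        solution, _, rank, _ = np.linalg.lstsq(A[:, trial], b, rcond=None)
        if rank < len(trial):
            warnings.warn(
                f"OMP: column {pick} is linearly dependent on the selected "
                "set; dropping it",
                RuntimeWarning,
                stacklevel=2,
            )
            dropped[pick] = True
            continue
        support = trial
        coef = solution
        residual = b - A[:, support] @ coef
        norms.append(float(np.linalg.norm(residual)))
        if norms[-1] <= eps:
            break

    alpha = np.zeros(n)
    if support:
        alpha[support] = coef
    return SparseSolution(
        alpha=alpha,
        support=np.array(support, dtype=int),
        residual_norm=norms[-1],
        residual_norms=norms,
    )


def gram_matrix(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """n x n kernel matrix over sample rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if spec.kind == "linear":
        return X @ X.T
    dist = pairwise_distances(X, metric=_DIST_METRICS[spec.metric])
    return np.exp(-dist / spec.delta)


def kernel_vector(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel evaluations between every row of ``X`` and the vector ``y``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(1, -1)
    if spec.kind == "linear":
        return (X @ y.T).ravel()
    dist = pairwise_distances(X, y, metric=_DIST_METRICS[spec.metric]).ravel()
    return np.exp(-dist / spec.delta)


def masked_residuals(
    A: np.ndarray, b: np.ndarray, alpha: np.ndarray, class_index: np.ndarray, n_classes: int
) -> np.ndarray:
    """Per-class reconstruction residuals ||b - A alpha_k||_2.

    ``alpha_k`` zeroes every coefficient not belonging to class k; the
    masked vectors sum exactly to ``alpha``.
    """
    residuals = np.empty(n_classes)
    for k in range(n_classes):
        masked = np.where(class_index == k, alpha, 0.0)
        residuals[k] = np.linalg.norm(b - A @ masked)
    return residuals


class _BaseSparseClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing for SRC and KSRC."""

    def __init__(self, sparsity: int = 50, tol: float = 1e-6):
        self.sparsity = sparsity
        self.tol = tol

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, class_index = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        if self.sparsity < 1:
            raise ValueError("sparsity must be at least 1")
        self._class_index = class_index
        self._fit_dictionary(X)
        return self

    def _fit_dictionary(self, X):  # pragma: no cover - abstract
        raise NotImplementedError

    def _code_one(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (A, b, alpha) of the sparse coding problem for one sample."""
        raise NotImplementedError

    def residuals(self, X) -> np.ndarray:
        """Per-class reconstruction residuals, shape (n_samples, n_classes)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        out = np.empty((X.shape[0], self.classes_.size))
        for i, x in enumerate(X):
            A, b, alpha = self._code_one(x)
            out[i] = masked_residuals(
                A, b, alpha, self._class_index, self.classes_.size
            )
        return out

    def predict(self, X):
        res = self.residuals(X)
        # argmin keeps the lowest class index on exact ties
        return self.classes_[np.argmin(res, axis=1)]

    def decision_function(self, X):
        """Residual margins; for binary problems, positive favours classes_[1]."""
        res = self.residuals(X)
        if self.classes_.size == 2:
            return res[:, 0] - res[:, 1]
        return -res


class SparseRepresentationClassifier(_BaseSparseClassifier):
    """SRC: sparse coding of test vectors over raw training columns.

    Parameters
    ----------
    sparsity : int
        OMP atom budget (the paper-style default is 50).
    tol : float
        Residual norm at which OMP stops early.
    normalize : bool
        l2-normalize dictionary columns before coding (standard practice;
        makes the correlation step scale-free).
    """

    def __init__(self, sparsity: int = 50, tol: float = 1e-6, normalize: bool = True):
        super().__init__(sparsity=sparsity, tol=tol)
        self.normalize = normalize

    def _fit_dictionary(self, X):
        dictionary = X.T.copy()  # columns are training samples
        if self.normalize:
            norms = np.linalg.norm(dictionary, axis=0)
            if np.any(norms == 0):
                raise ValueError("cannot normalize an all-zero training sample")
            dictionary = dictionary / norms
        self.dictionary_ = dictionary

    def _code_one(self, x):
        solution = omp(self.dictionary_, x, self.sparsity, self.tol)
        return self.dictionary_, x, solution.alpha


class KernelSparseRepresentationClassifier(_BaseSparseClassifier):
    """KSRC: sparse coding in the kernel Gram-matrix linear system.

    Parameters
    ----------
    delta : float or "median"
        Laplacian bandwidth; ``"median"`` uses the median pairwise
        training distance (a standard bandwidth heuristic).
    kernel : {"laplacian", "linear"}
    metric : {"l2", "l1"}
        Distance inside the Laplacian kernel.
    sparsity, tol
        OMP budget and early-stop tolerance, as for SRC.

    Attributes
    ----------
    delta_ : float
        Bandwidth actually used (resolved from the heuristic if requested).
    gram_ : ndarray
        Kernel matrix of the training samples (the OMP dictionary).
    """

    def __init__(
        self,
        delta: float | str = 100.0,
        kernel: str = "laplacian",
        metric: str = "l2",
        sparsity: int = 50,
        tol: float = 1e-6,
    ):
        super().__init__(sparsity=sparsity, tol=tol)
        self.delta = delta
        self.kernel = kernel
        self.metric = metric

    def _resolve_delta(self, X) -> float:
        if self.delta == "median":
            dist = pairwise_distances(X, metric=_DIST_METRICS[self.metric])
            off_diag = dist[np.triu_indices_from(dist, k=1)]
            median = float(np.median(off_diag))
            if median <= 0:
                raise ValueError("median pairwise distance is zero; set delta explicitly")
            return median
        return float(self.delta)

    def _fit_dictionary(self, X):
        self.X_train_ = X
        delta = self._resolve_delta(X) if self.kernel == "laplacian" else 1.0
        self.delta_ = delta
        self.kernel_spec_ = KernelSpec(kind=self.kernel, delta=delta, metric=self.metric)
        self.gram_ = gram_matrix(X, self.kernel_spec_)

    def _code_one(self, x):
        b = kernel_vector(self.X_train_, x, self.kernel_spec_)
        solution = omp(self.gram_, b, self.sparsity, self.tol)
        return self.gram_, b, solution.alpha


def src_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    y: np.ndarray,
    k: int = 50,
    eps: float = 1e-6,
    normalize: bool = True,
):
    """One-shot SRC decision for a single test vector.

    Returns ``(predicted class, per-class residuals)``; thin wrapper over
    :class:`SparseRepresentationClassifier`.
    """
    clf = SparseRepresentationClassifier(sparsity=k, tol=eps, normalize=normalize)
    clf.fit(X_train, y_train)
    res = clf.residuals(np.atleast_2d(y))[0]
    return clf.classes_[int(np.argmin(res))], res


def ksrc_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec = KernelSpec(),
    k: int = 50,
    eps: float = 1e-6,
):
    """One-shot KSRC decision for a single test vector."""
    clf = KernelSparseRepresentationClassifier(
        delta=spec.delta, kernel=spec.kind, metric=spec.metric, sparsity=k, tol=eps
    )
    clf.fit(X_train, y_train)
    res = clf.residuals(np.atleast_2d(y))[0]
    return clf.classes_[int(np.argmin(res))], res


# ---------------------------------------------------------------------------
# Model persistence (plain-text directory format)
# ---------------------------------------------------------------------------

def save_model(
    directory: str | Path,
    clf: _BaseSparseClassifier,
    feature_names: list[str] | None = None,
) -> None:
    """Persist a fitted SRC/KSRC model as a plain-text directory.

    Layout: ``dictionary.tsv`` (training samples, one row each),
    ``classes.tsv`` (per-sample class), ``config.txt`` (key=value
    hyperparameters), and optionally ``features.txt`` (column names the
    model expects, in order).
    """
    check_is_fitted(clf)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    if isinstance(clf, KernelSparseRepresentationClassifier):
        samples = clf.X_train_
        config = {
            "model": "ksrc",
            "kernel": clf.kernel,
            "delta": repr(clf.delta_),
            "metric": clf.metric,
            "sparsity": str(clf.sparsity),
            "tol": repr(clf.tol),
        }
    elif isinstance(clf, SparseRepresentationClassifier):
        # store raw samples; normalization is re-applied on load
        samples = clf.dictionary_.T
        config = {
            "model": "src",
            "normalize": str(clf.normalize),
            "sparsity": str(clf.sparsity),
            "tol": repr(clf.tol),
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot persist {type(clf).__name__}")

    np.savetxt(directory / "dictionary.tsv", samples, delimiter="\t", fmt="%.12g")
    labels = clf.classes_[clf._class_index]
    np.savetxt(directory / "classes.tsv", labels, delimiter="\t", fmt="%d")
    (directory / "config.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in config.items())
    )
    if feature_names is not None:
        (directory / "features.txt").write_text("\n".join(feature_names) + "\n")


def load_model(directory: str | Path) -> _BaseSparseClassifier:
    """Load a model saved by :func:`save_model` and refit its dictionary."""
    directory = Path(directory)
    config = {}
    for line in (directory / "config.txt").read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            config[key.strip()] = value.strip()
    samples = np.loadtxt(directory / "dictionary.tsv", delimiter="\t", ndmin=2)
    labels = np.loadtxt(directory / "classes.tsv", ndmin=1).astype(int)

    if config["model"] == "ksrc":
        clf = KernelSparseRepresentationClassifier(
            delta=float(config["delta"]),
            kernel=config["kernel"],
            metric=config["metric"],
            sparsity=int(config["sparsity"]),
            tol=float(config["tol"]),
        )
    elif config["model"] == "src":
        clf = SparseRepresentationClassifier(
            sparsity=int(config["sparsity"]),
            tol=float(config["tol"]),
            normalize=config["normalize"] == "True",
        )
    else:
        raise ValueError(f"unknown model kind {config.get('model')!r}")
    clf.fit(samples, labels)
    return clf


def load_model_feature_names(directory: str | Path) -> list[str] | None:
    path = Path(directory) / "features.txt"
    if not path.exists():
        return None
    return [line for line in path.read_text().splitlines() if line]
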