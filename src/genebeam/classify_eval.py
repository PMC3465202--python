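"""Wrapped classifiers and cross-validated evaluation statistics.

Two classifiers score candidate gene subsets: 5-nearest-neighbors with
Euclidean distance, and an RBF-kernel support-vector classifier whose
(C, gamma) pair is grid-searched over C in {200, 400} and gamma spanning
[1e-5, 10].  Acc(T) is stratified k-fold cross-validated accuracy on the
training set restricted to the subset T.  The Full-fold CV statistic
summarizes CV(k) for every fold count k = 2..m:

    mean = (1 / (m - 1)) * sum_{k=2}^{m} CV(k)
    std  = sqrt( sum_{k=2}^{m} (CV(k) - mean)^2 / (m - 2) )

Accuracies are stored as fractions in [0, 1] throughout; reports render
them as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from genebeam.io_norm import ExpressionDataset

__all__ = [
    "ClassifierSpec",
    "FullFoldResult",
    "MetricSet",
    "knn_predict",
    "cv_accuracy",
    "full_fold_cv",
    "recommended_max_subset_size",
    "metrics_from_counts",
    "roc_auc",
    "stratified_folds",
]


def default_gamma_grid() -> tuple[float, ...]:
    """gamma in {a * 10^e : a = 1..9, e = -5..-1} union {1, ..., 10}."""
    grid = [a * 10.0 ** e for e in range(-5, 0) for a in range(1, 10)]
    grid.extend(float(g) for g in range(1, 11))
    return tuple(grid)


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the wrapped classifier and its cross-validation.

    Parameters
    ----------
    kind : {"knn", "svm_rbf"}
    knn_k : odd int
        Neighbor count; odd to avoid tied votes in binary problems.
    svm_C_grid, svm_gamma_grid : sequences of positive floats
        The (C, gamma) grid searched for svm_rbf; the returned accuracy is
        the maximum over the grid.
    cv_folds : int
        Fold count for Acc(T); 10 by default.
    seed : int
        Seeds the stratified fold partition.
    """

    kind: str = "knn"
    knn_k: int = 5
    svm_C_grid: tuple[float, ...] = (200.0, 400.0)
    svm_gamma_grid: tuple[float, ...] = field(default_factory=default_gamma_grid)
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm_rbf"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be an odd positive integer")
        object.__setattr__(self, "svm_C_grid", tuple(self.svm_C_grid))
        object.__setattr__(self, "svm_gamma_grid", tuple(self.svm_gamma_grid))
        if any(c <= 0 for c in self.svm_C_grid):
            raise ValueError("C grid values must be positive")
        if any(g <= 0 for g in self.svm_gamma_grid):
            raise ValueError("gamma grid values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    def grid_pairs(self) -> list[tuple[float, float]]:
        """(gamma, C) pairs in deterministic tie-break order."""
        return [
            (g, c)
            for g in sorted(self.svm_gamma_grid)
            for c in sorted(self.svm_C_grid)
        ]


@dataclass(frozen=True)
class FullFoldResult:
    """CV(k) for k = 2..m with the Full-fold mean and standard deviation."""

    per_k: dict[int, float]
    mean: float
    std: float

    @classmethod
    def from_accuracies(cls, per_k: dict[int, float]) -> "FullFoldResult":
        """Aggregate a map k -> CV(k), k = 2..m, into mean and std.

        The mean divides by m - 1 (the number of fold counts) and the
        standard deviation uses denominator m - 2.
        """
        ks = sorted(per_k)
        if len(ks) < 2:
            raise ValueError("need CV(k) for at least k = 2 and 3")
        if ks != list(range(2, ks[-1] + 1)):
            raise ValueError("per_k must cover every k in 2..m")
        accs = np.array([per_k[k] for k in ks])
        if np.any((accs < 0) | (accs > 1)):
            raise ValueError("CV(k) accuracies must lie in [0, 1]")
        m = ks[-1]
        mean = accs.sum() / (m - 1)
        std = float(np.sqrt(((accs - mean) ** 2).sum() / (m - 2)))
        return cls(per_k=dict(per_k), mean=float(mean), std=std)


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived rates; undefined rates are None."""

    TP: int
    TN: int
    FP: int
    FN: int
    acc: float
    sp: float | None
    tpr: float | None
    fpr: float | None
    ppv: float | None
    npv: float | None


def _encode_labels(labels, classes) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[l] for l in labels], dtype=int)


def _knn_predict_codes(
    train_X: np.ndarray,
    train_codes: np.ndarray,
    query_X: np.ndarray,
    k: int,
    n_classes: int,
) -> np.ndarray:
    """k-NN majority vote on encoded labels.

    Multi-class vote ties are broken by the class of the nearest neighbor
    among the tied classes.  Neighbor-distance ties are broken by training
    sample order (stable sort), which makes the prediction invariant to
    permutations of the training set only up to exact distance ties.
    """
    if k > train_X.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {train_X.shape[0]} training samples"
        )
    dist = cdist(query_X, train_X, metric="euclidean")
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    out = np.empty(query_X.shape[0], dtype=int)
    for i, neigh in enumerate(nearest):
        votes = np.bincount(train_codes[neigh], minlength=n_classes)
        top = votes.max()
        tied = np.nonzero(votes == top)[0]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            tied_set = set(tied.tolist())
            out[i] = next(
                c for c in train_codes[neigh] if c in tied_set
            )
    return out


def knn_predict(train: ExpressionDataset, query, k: int | None = None):
    """Labels of query sample vectors by Euclidean k-NN majority vote."""
    if k is None:
        k = 5
    query = np.atleast_2d(np.asarray(query, dtype=float))
    if query.shape[1] != train.n:
        raise ValueError(
            f"query has {query.shape[1]} features, training set has {train.n}"
        )
    classes = train.classes
    codes = _knn_predict_codes(
        train.values,
        _encode_labels(train.labels, classes),
        query,
        k,
        len(classes),
    )
    return [classes[c] for c in codes]


def stratified_folds(
    labels, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified (train, test) index pairs.

    A fixed partition per seed: the subset search evaluates every candidate
    subset against the same folds, so its accuracy trace is coherent.
    Stratification needs at least one member of every class per fold; for
    fold counts beyond the smallest class (the high-k end of Full-fold CV,
    up to leave-one-out) a plain shuffled partition is used instead.
    """
    labels = np.asarray(labels)
    if n_folds > labels.size:
        raise ValueError("more folds than samples")
    _, counts = np.unique(labels, return_counts=True)
    if n_folds <= counts.min():
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (tr, te) for tr, te in splitter.split(np.zeros(labels.size), labels)
    ]


def _zscore_block(train_block: np.ndarray, test_block: np.ndarray):
    mean = train_block.mean(axis=0)
    std = train_block.std(axis=0, ddof=1) if train_block.shape[0] > 1 else None
    if std is None:
        return train_block - mean, test_block - mean
    safe = np.where(std > 0, std, 1.0)
    tr = (train_block - mean) / safe
    te = (test_block - mean) / safe
    tr[:, std == 0] = 0.0
    te[:, std == 0] = 0.0
    return tr, te


def _svm_grid_fold_accuracies(
    X: np.ndarray,
    codes: np.ndarray,
    folds,
    spec: ClassifierSpec,
    normalize_per_fold: bool,
) -> list[tuple[tuple[float, float], float]]:
    """CV accuracy for each (gamma, C) pair, in grid tie-break order."""
    pairs = spec.grid_pairs()
    correct = np.zeros(len(pairs))
    total = 0
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        if normalize_per_fold:
            Xtr, Xte = _zscore_block(Xtr, Xte)
        total += te.size
        for idx, (gamma, c) in enumerate(pairs):
            clf = SVC(kernel="rbf", C=c, gamma=gamma)
            clf.fit(Xtr, codes[tr])
            correct[idx] += int((clf.predict(Xte) == codes[te]).sum())
    return [(pair, correct[i] / total) for i, pair in enumerate(pairs)]


def cv_accuracy(
    ds: ExpressionDataset,
    subset,
    spec: ClassifierSpec,
    folds=None,
    normalize_per_fold: bool = False,
) -> float:
    """Stratified k-fold CV accuracy Acc(T) of a gene subset.

    For svm_rbf the returned accuracy is the maximum over the (C, gamma)
    grid.  ``folds`` may carry a precomputed partition (one fixed partition
    per search run); otherwise folds are drawn from ``spec.seed``.  With
    ``normalize_per_fold`` the restricted column block is z-scored using
    fold-training statistics before each evaluation (leakage-safe mode);
    the default assumes the caller normalized the training set once.
    """
    genes = tuple(getattr(subset, "genes", subset))
    sub = ds.restrict(genes)
    classes = sub.classes
    codes = _encode_labels(sub.labels, classes)
    if folds is None:
        folds = stratified_folds(sub.labels, spec.cv_folds, spec.seed)
    if spec.kind == "svm_rbf":
        accs = _svm_grid_fold_accuracies(
            sub.values, codes, folds, spec, normalize_per_fold
        )
        return max(acc for _, acc in accs)
    correct = 0
    total = 0
    for tr, te in folds:
        Xtr, Xte = sub.values[tr], sub.values[te]
        if normalize_per_fold:
            Xtr, Xte = _zscore_block(Xtr, Xte)
        pred = _knn_predict_codes(
            Xtr, codes[tr], Xte, min(spec.knn_k, tr.size), len(classes)
        )
        correct += int((pred == codes[te]).sum())
        total += te.size
    return correct / total


def full_fold_cv(
    ds: ExpressionDataset, subset, spec: ClassifierSpec
) -> FullFoldResult:
    """CV(k) for every fold count k = 2..m, aggregated per the Full-fold
    mean/std definitions (k = m is leave-one-out)."""
    if ds.m < 3:
        raise ValueError("Full-fold CV needs at least 3 samples")
    per_k = {}
    for k in range(2, ds.m + 1):
        folds = stratified_folds(ds.labels, k, spec.seed)
        per_k[k] = cv_accuracy(ds, subset, spec, folds=folds)
    return FullFoldResult.from_accuracies(per_k)


def recommended_max_subset_size(m_t: int, k: int) -> int:
    """Largest subset size n_s honoring the five-samples-per-feature rule
    (m_t / k) / n_s > 5.

    Returns floor(m_t / (5 k)).  When m_t / (5 k) is an exact integer the
    returned size sits on the boundary of the strict inequality; a warning
    flags it.
    """
    if m_t < 5 * k:
        raise ValueError(
            f"{m_t} training samples over {k} classes admit no subset size"
        )
    size = m_t // (5 * k)
    if m_t == 5 * k * size:
        warnings.warn(
            f"subset size {size} sits exactly on the 5-samples-per-feature "
            "boundary",
            stacklevel=2,
        )
    return size


def metrics_from_counts(TP: int, TN: int, FP: int, FN: int) -> MetricSet:
    """Accuracy, specificity, TPR, FPR, PPV and NPV from confusion counts.

    A rate whose denominator is zero is reported as None, never as 0.
    """
    counts = (TP, TN, FP, FN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")

    def rate(num, den):
        return num / den if den > 0 else None

    sp = rate(TN, FP + TN)
    return MetricSet(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        acc=(TP + TN) / total,
        sp=sp,
        tpr=rate(TP, TP + FN),
        fpr=None if sp is None else 1.0 - sp,
        ppv=rate(TP, TP + FP),
        npv=rate(TN, TN + FN),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties between scores count one half.

    Equals the probability that a positive sample outscores a negative one
    (the Mann-Whitney statistic with the midrank tie convention).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC analysis needs exactly two classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
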