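"""Majority-voting ensemble classifier built from the optimal gene subsets.

Each optimal subset trains one individual classifier on the full training
set restricted to that subset; a test sample's label is the simple majority
of the N individual votes.  The reliability of each decision is the
confidence level

    conf = m_max / m_sec,

the ratio of the largest to the second-largest vote count; a unanimous vote
(m_sec = 0) gets conf = N, so conf always lies in [1, N].

For the RBF-SVM ensemble two hyperparameter-selection modes exist.  The
unbiased mode picks each classifier's (C, gamma) by training-set CV alone
(deterministic grid-order tie-break) and is the honest generalization
estimate.  The biased mode starts from the same training-CV-optimal ties
but resolves them with test-set accuracy, quantifying how much selection
bias inflates the result; its output is always labeled "biased".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

from genebeam.classify_eval import (
    ClassifierSpec,
    _encode_labels,
    _knn_predict_codes,
    _svm_grid_fold_accuracies,
    stratified_folds,
)
from genebeam.io_norm import ExpressionDataset
from genebeam.search import GeneSubset, OptimalSubsets

__all__ = [
    "VoteVector",
    "EnsembleResult",
    "confidence",
    "shared_subsets",
    "ensemble_predict",
]


@dataclass(frozen=True)
class VoteVector:
    """Per-class vote counts (m_1, ..., m_k) with the confidence level."""

    counts: tuple[int, ...]
    N: int
    m_max: int
    m_sec: int
    conf: float

    @classmethod
    def from_counts(cls, counts) -> "VoteVector":
        counts = tuple(int(c) for c in counts)
        if any(c < 0 for c in counts):
            raise ValueError("negative vote count")
        total = sum(counts)
        if total < 1:
            raise ValueError("empty vote vector")
        ordered = sorted(counts, reverse=True)
        m_max = ordered[0]
        m_sec = ordered[1] if len(ordered) > 1 else 0
        conf = m_max / m_sec if m_sec > 0 else float(total)
        return cls(
            counts=counts, N=total, m_max=m_max, m_sec=m_sec, conf=conf
        )


def confidence(counts, N: int | None = None) -> float:
    """Confidence level conf = m_max / m_sec of a vote vector.

    If the second-largest count is zero (unanimous vote) conf equals N,
    the ensemble size.  Reports render conf to 4 decimal places.
    """
    vv = VoteVector.from_counts(counts)
    if N is not None and N != vv.N:
        raise ValueError(f"counts sum to {vv.N}, expected N={N}")
    return vv.conf


@dataclass(frozen=True)
class SamplePrediction:
    sample_id: str
    predicted: str
    true_label: str
    votes: VoteVector
    correct: bool


@dataclass(frozen=True)
class EnsembleResult:
    """Per-sample ensemble votes and the overall test accuracy."""

    per_sample: tuple[SamplePrediction, ...]
    accuracy: float
    mode: str
    n_classifiers: int


def shared_subsets(
    optimal: OptimalSubsets, test: ExpressionDataset
) -> OptimalSubsets:
    """Subsets whose every gene is present on the test platform.

    Cross-platform test sets measure only part of the training platform's
    genes, so only the surviving subsets can vote.
    """
    present = set(test.gene_ids)
    kept = tuple(
        s for s in optimal.subsets if all(g in present for g in s.genes)
    )
    if not kept:
        raise ValueError("no subset is fully covered by the test platform")
    return replace(optimal, subsets=kept)


def _svm_pick_and_predict(
    Xtr: np.ndarray,
    codes_tr: np.ndarray,
    Xte: np.ndarray,
    codes_te: np.ndarray,
    spec: ClassifierSpec,
    folds,
    biased: bool,
) -> np.ndarray:
    """Choose (C, gamma) and predict the test samples.

    Both modes restrict attention to the grid pairs that maximize training
    CV accuracy.  Unbiased takes the first such pair in grid order; biased
    takes, among those ties, the pair with the highest test accuracy.
    """
    grid = _svm_grid_fold_accuracies(Xtr, codes_tr, folds, spec, False)
    best_cv = max(acc for _, acc in grid)
    tied = [pair for pair, acc in grid if acc == best_cv]
    if not biased:
        chosen = tied[0]
        gamma, c = chosen
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
        clf.fit(Xtr, codes_tr)
        return clf.predict(Xte)
    best_pred = None
    best_acc = -1.0
    for gamma, c in tied:
        clf = SVC(kernel="rbf", C=c, gamma=gamma)
        clf.fit(Xtr, codes_tr)
        pred = clf.predict(Xte)
        acc = float((pred == codes_te).mean())
        if acc > best_acc:
            best_acc, best_pred = acc, pred
    return best_pred


def ensemble_predict(
    train: ExpressionDataset,
    test: ExpressionDataset,
    subsets: OptimalSubsets,
    spec: ClassifierSpec,
    mode: str = "unbiased",
) -> EnsembleResult:
    """Classify the test set with the majority vote of per-subset
    classifiers.

    Every subset must already have passed :func:`shared_subsets`.  Vote
    ties are broken toward the class listed first in the training label
    set, with conf recorded as 1 (m_max = m_sec).  ``mode="biased"``
    applies only to svm_rbf; a biased KNN has no hyperparameter grid to
    overfit.
    """
    if mode not in ("biased", "unbiased"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "biased" and spec.kind != "svm_rbf":
        raise ValueError(
            "biased mode is an SVM parameter-selection phenomenon; "
            "it does not apply to knn"
        )
    if not subsets.subsets:
        raise ValueError("no subsets to build an ensemble from")
    classes = train.classes
    class_idx = {c: i for i, c in enumerate(classes)}
    codes_te_true = np.array(
        [class_idx[l] for l in test.labels], dtype=int
    )
    votes = np.zeros((test.m, len(classes)), dtype=int)
    folds = (
        stratified_folds(train.labels, spec.cv_folds, spec.seed)
        if spec.kind == "svm_rbf"
        else None
    )
    for subset in subsets.subsets:
        genes = subset.genes
        tr = train.restrict(genes)
        te = test.restrict(genes)
        codes_tr = _encode_labels(tr.labels, classes)
        if spec.kind == "svm_rbf":
            pred = _svm_pick_and_predict(
                tr.values, codes_tr, te.values, codes_te_true, spec,
                folds, biased=(mode == "biased"),
            )
        else:
            pred = _knn_predict_codes(
                tr.values, codes_tr, te.values, spec.knn_k, len(classes)
            )
        votes[np.arange(test.m), pred] += 1

    per_sample = []
    n_correct = 0
    for i, sid in enumerate(test.sample_ids):
        vv = VoteVector.from_counts(votes[i])
        # ties go to the first class in label order (argmax is first max)
        pred_label = classes[int(np.argmax(votes[i]))]
        ok = pred_label == test.labels[i]
        n_correct += ok
        per_sample.append(
            SamplePrediction(
                sample_id=sid,
                predicted=pred_label,
                true_label=test.labels[i],
                votes=vv,
                correct=bool(ok),
            )
        )
    return EnsembleResult(
        per_sample=tuple(per_sample),
        accuracy=n_correct / test.m,
        mode=mode,
        n_classifiers=len(subsets.subsets),
    )
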