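"""Occurrence-frequency gene ranking and the power-law diagnostic.

A gene's importance is measured by how many optimal subsets contain it,
accumulated over all search runs.  Empirically the resulting frequencies
fall off roughly as a power of the rank order, so only a handful of
top-ranked genes carry most of the signal; the diagnostic fits an ordinary
least-squares line to log(frequency) versus log(rank).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from genebeam.classify_eval import (
    ClassifierSpec,
    _encode_labels,
    _knn_predict_codes,
    _svm_grid_fold_accuracies,
    stratified_folds,
)
from genebeam.io_norm import ExpressionDataset
from genebeam.prefilter import GeneRanking
from genebeam.search import OptimalSubsets
from sklearn.svm import SVC

__all__ = [
    "FrequencyTable",
    "PowerLawFit",
    "gene_frequency",
    "top_genes",
    "accuracy_vs_topk",
    "powerlaw_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTable:
    """Gene occurrence counts in table order: count descending, ties by
    KWRST p-value ascending, then by gene id."""

    gene_ids: tuple[str, ...]
    counts: tuple[int, ...]
    pvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.gene_ids) == len(self.counts) == len(self.pvalues)
        ):
            raise ValueError("column length mismatch")
        if any(c < 1 for c in self.counts):
            raise ValueError("every listed gene must occur at least once")

    def __len__(self) -> int:
        return len(self.gene_ids)


def gene_frequency(
    runs, ranking: GeneRanking | None = None
) -> FrequencyTable:
    """Count each gene's occurrences over all subsets of all runs.

    ``runs`` is an iterable of OptimalSubsets (e.g. the five KNN-wrapped
    search runs); a gene appearing in several runs' subsets accumulates
    across runs.  Ties in count are broken by KWRST p-value ascending when
    a ranking is supplied, then by gene id.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs supplied")
    counts: dict[str, int] = {}
    for run in runs:
        for subset in run.subsets:
            for g in subset.genes:
                counts[g] = counts.get(g, 0) + 1
    if ranking is not None:
        pmap = dict(zip(ranking.gene_ids, ranking.pvalues))
        pvals = {g: float(pmap.get(g, 1.0)) for g in counts}
    else:
        pvals = {g: 1.0 for g in counts}
    order = sorted(counts, key=lambda g: (-counts[g], pvals[g], g))
    return FrequencyTable(
        gene_ids=tuple(order),
        counts=tuple(counts[g] for g in order),
        pvalues=tuple(pvals[g] for g in order),
    )


def top_genes(ft: FrequencyTable, n: int) -> list[str]:
    """The first n genes in table order."""
    if n < 1:
        raise ValueError("n must be positive")
    if n > len(ft):
        raise ValueError(f"n={n} exceeds the {len(ft)} ranked genes")
    return list(ft.gene_ids[:n])


def accuracy_vs_topk(
    train: ExpressionDataset,
    test: ExpressionDataset,
    ft: FrequencyTable,
    spec: ClassifierSpec,
    ks,
) -> dict[int, float]:
    """Test accuracy of a classifier trained on the top-k ranked genes.

    Genes absent from the test platform are skipped and backfilled with the
    next-ranked gene (the cross-platform convention); substitutions are
    logged.  Returns a map k -> test accuracy fraction.
    """
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 1:
        raise ValueError("k values must be positive")
    present = set(test.gene_ids) & set(train.gene_ids)
    usable = [g for g in ft.gene_ids if g in present]
    skipped = [g for g in ft.gene_ids if g not in present]
    if not usable:
        raise ValueError("no ranked gene is shared by train and test")
    if skipped:
        logger.info(
            "%d ranked genes absent from the test platform were skipped "
            "(next-ranked genes substituted): %s",
            len(skipped), ", ".join(skipped[:10]),
        )
    if ks[-1] > len(usable):
        raise ValueError(
            f"k={ks[-1]} exceeds the {len(usable)} shared ranked genes"
        )
    classes = train.classes
    curve: dict[int, float] = {}
    for k in ks:
        genes = usable[:k]
        tr = train.restrict(genes)
        te = test.restrict(genes)
        codes_tr = _encode_labels(tr.labels, classes)
        codes_te = _encode_labels(te.labels, classes)
        if spec.kind == "svm_rbf":
            folds = stratified_folds(tr.labels, spec.cv_folds, spec.seed)
            grid = _svm_grid_fold_accuracies(
                tr.values, codes_tr, folds, spec, False
            )
            best_cv = max(acc for _, acc in grid)
            gamma, c = next(p for p, acc in grid if acc == best_cv)
            clf = SVC(kernel="rbf", C=c, gamma=gamma)
            clf.fit(tr.values, codes_tr)
            pred = clf.predict(te.values)
        else:
            pred = _knn_predict_codes(
                tr.values, codes_tr, te.values, spec.knn_k, len(classes)
            )
        curve[k] = float((pred == codes_te).mean())
    return curve


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log(frequency) on log(rank); slope = -exponent."""

    slope: float
    intercept: float
    r2: float


def powerlaw_fit(ft: FrequencyTable) -> PowerLawFit:
    """Least-squares line through (log rank, log frequency).

    Rank runs 1..len(table) in table order.  A frequency table following an
    exact power law C * rank^(-alpha) is recovered with slope -alpha and
    r^2 = 1.
    """
    if len(ft) < 3:
        raise ValueError("power-law fit needs at least 3 ranked genes")
    ranks = np.arange(1, len(ft) + 1, dtype=float)
    freqs = np.asarray(ft.counts, dtype=float)
    res = stats.linregress(np.log(ranks), np.log(freqs))
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )
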