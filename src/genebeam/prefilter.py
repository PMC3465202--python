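"""Kruskal-Wallis pre-filtering of candidate genes.

Tumor expression data are rarely Gaussian, so genes are pre-ranked with the
nonparametric Kruskal-Wallis rank sum test (KWRST), which handles any
number of classes and small samples.  Only the p top-ranked genes enter the
subset search; for two classes KWRST is equivalent to the two-sided
Wilcoxon rank-sum test (H = Z^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from genebeam.io_norm import ExpressionDataset

__all__ = ["GeneRanking", "kwrst_pvalues", "preselect"]


@dataclass(frozen=True)
class GeneRanking:
    """Per-gene KWRST p-values with a deterministic ascending order.

    ``order`` is a permutation of column indices sorting p-values
    ascending; ties are broken by original column index (stable sort).
    """

    gene_ids: tuple[str, ...]
    pvalues: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = np.asarray(self.pvalues, dtype=float)
        object.__setattr__(self, "pvalues", p)
        object.__setattr__(
            self, "order", np.asarray(self.order, dtype=int)
        )
        if len(self.gene_ids) != p.size:
            raise ValueError("gene_ids and pvalues length mismatch")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values outside [0, 1]")
        if sorted(self.order) != list(range(p.size)):
            raise ValueError("order is not a permutation")

    def rank_of(self, gene_id: str) -> int:
        """0-based KWRST rank of a gene (0 = smallest p-value)."""
        col = self.gene_ids.index(gene_id)
        return int(np.nonzero(self.order == col)[0][0])


def kwrst_pvalues(ds: ExpressionDataset) -> GeneRanking:
    """Kruskal-Wallis H test per gene, chi-square p-value with k-1 df.

    The H statistic is tie-corrected.  A gene constant across all samples
    carries no rank information; its p-value is set to 1.
    """
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    labels = np.asarray(ds.labels)
    groups = [np.nonzero(labels == c)[0] for c in classes]
    for c, idx in zip(classes, groups):
        if idx.size == 0:
            raise ValueError(f"class {c!r} has no samples")
    pvals = np.empty(ds.n)
    for j in range(ds.n):
        col = ds.values[:, j]
        if np.all(col == col[0]):
            pvals[j] = 1.0
            continue
        _, pvals[j] = stats.kruskal(*(col[idx] for idx in groups))
    order = np.argsort(pvals, kind="stable")
    return GeneRanking(gene_ids=ds.gene_ids, pvalues=pvals, order=order)


def preselect(ranking: GeneRanking, p: int) -> list[str]:
    """The p genes with the smallest p-values, ties by column index."""
    n = len(ranking.gene_ids)
    if p < 1:
        raise ValueError("p must be positive")
    if p > n:
        raise ValueError(f"p={p} exceeds the {n} available genes")
    return [ranking.gene_ids[j] for j in ranking.order[:p]]
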