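"""Expression matrix I/O, per-gene normalization, and cross-platform alignment.

On disk, expression matrices follow the microarray convention of genes as
rows (first column ``gene_id``, header row of sample ids).  In memory the
matrix is samples x genes, matching the usual GEP formulation X = (x_ij)
with m samples and n genes.  Labels live in a separate two-column TSV
mapping sample id to class and are matched by id, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "write_labels",
    "zscore_normalize",
    "minmax_normalize",
    "align_cross_platform",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """A labeled samples x genes expression matrix.

    Attributes
    ----------
    sample_ids : tuple of str
        Unique sample identifiers; length m.
    gene_ids : tuple of str
        Unique gene identifiers; length n.
    values : ndarray of shape (m, n)
        Expression levels x_ij in arbitrary platform units; all finite.
    labels : tuple of str
        Per-sample class labels; every class occurs at least once.
    """

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        m, n = values.shape
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {m} matrix rows"
            )
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} matrix columns"
            )
        if len(self.labels) != m:
            raise ValueError(f"{len(self.labels)} labels for {m} samples")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite expression values")

    @property
    def m(self) -> int:
        """Number of samples."""
        return len(self.sample_ids)

    @property
    def n(self) -> int:
        """Number of genes."""
        return len(self.gene_ids)

    @property
    def classes(self) -> tuple[str, ...]:
        """Label set L in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def k(self) -> int:
        """Number of classes."""
        return len(self.classes)

    def gene_index(self, gene_ids) -> np.ndarray:
        """Column indices for the given gene ids; raises on unknown ids."""
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def restrict(self, gene_ids) -> "ExpressionDataset":
        """Dataset restricted to the given genes, in the given order."""
        idx = self.gene_index(gene_ids)
        return replace(
            self, gene_ids=tuple(gene_ids), values=self.values[:, idx]
        )


def read_expression(path, labels_path) -> ExpressionDataset:
    """Read a genes-as-rows expression TSV plus a sample-label TSV.

    The expression file must have a header row of sample ids with the first
    column named ``gene_id``.  Labels are matched to samples by id; a sample
    present in only one of the two files is an error.
    """
    path, labels_path = Path(path), Path(labels_path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    for col in frame.columns:
        if frame[col].dtype.kind in "fiu":
            continue
        # a non-numeric cell forces the whole column to object dtype;
        # locate the cell that actually fails to parse
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ValueError(
                f"non-numeric value at gene {row!r}, sample {col!r} in {path}"
            )
        frame[col] = coerced
    labels_frame = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample_id", "class"],
        dtype=str,
    )
    if labels_frame["sample_id"].duplicated().any():
        dup = labels_frame["sample_id"][
            labels_frame["sample_id"].duplicated()
        ].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in {labels_path}")
    label_map = dict(
        zip(labels_frame["sample_id"], labels_frame["class"])
    )
    samples = list(frame.columns)
    missing = [s for s in samples if s not in label_map]
    if missing:
        raise ValueError(
            f"sample {missing[0]!r} has no label in {labels_path}"
        )
    extra = set(label_map) - set(samples)
    if extra:
        raise ValueError(
            f"label for unknown sample {sorted(extra)[0]!r} in {labels_path}"
        )
    return ExpressionDataset(
        sample_ids=tuple(samples),
        gene_ids=tuple(frame.index),
        values=frame.to_numpy(dtype=float).T,
        labels=tuple(label_map[s] for s in samples),
    )


def write_expression(ds: ExpressionDataset, path) -> None:
    """Write the expression matrix as a genes-as-rows TSV.

    Values are rendered with 17 significant digits so a read/write round
    trip is lossless for doubles.
    """
    frame = pd.DataFrame(
        ds.values.T, index=list(ds.gene_ids), columns=list(ds.sample_ids)
    )
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_labels(ds: ExpressionDataset, path) -> None:
    """Write the sample-to-class mapping as a two-column TSV."""
    pd.DataFrame(
        {"sample_id": list(ds.sample_ids), "class": list(ds.labels)}
    ).to_csv(path, sep="\t", header=False, index=False)


def zscore_normalize(
    ds: ExpressionDataset,
    reference: ExpressionDataset | None = None,
) -> ExpressionDataset:
    """Per-gene z-score normalization: mean 0, standard deviation 1.

    Uses the sample standard deviation (denominator m - 1).  Constant gene
    columns map to all-zeros.  If ``reference`` is given, its per-gene
    statistics are applied instead of the dataset's own (for normalizing a
    test platform with training-set statistics); the default normalizes each
    dataset independently.
    """
    if ds.m < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    src = reference if reference is not None else ds
    mean = src.values.mean(axis=0)
    std = src.values.std(axis=0, ddof=1)
    out = np.zeros_like(ds.values)
    nonconst = std > 0
    out[:, nonconst] = (ds.values[:, nonconst] - mean[nonconst]) / std[nonconst]
    return replace(ds, values=out)


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-gene 0-1 scaling: x -> (x - min) / (max - min).

    Constant gene columns map to 0.5 (the midpoint of the target range).
    """
    if ds.m < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    lo = ds.values.min(axis=0)
    hi = ds.values.max(axis=0)
    span = hi - lo
    out = np.full_like(ds.values, 0.5)
    nonconst = span > 0
    out[:, nonconst] = (ds.values[:, nonconst] - lo[nonconst]) / span[nonconst]
    return replace(ds, values=out)


def align_cross_platform(
    train: ExpressionDataset, test: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset, int]:
    """Restrict both datasets to their shared genes, in identical order.

    The shared genes are sorted lexicographically so the two platforms end
    up with the same column layout.  Returns ``(train, test, n_shared)``.
    """
    shared = sorted(set(train.gene_ids) & set(test.gene_ids))
    if not shared:
        raise ValueError("no shared genes between the two platforms")
    return train.restrict(shared), test.restrict(shared), len(shared)
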