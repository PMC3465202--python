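"""Heuristic breadth-first beam search over gene subsets.

The search grows gene subsets one gene per layer.  Layer 1 holds the p
pre-selected singletons; each later layer scores the classification matrix
CM whose cell (i, j) is Acc(Row[i] union Column[j]) -- the cross-validated
accuracy of extending beam subset i with candidate gene j -- and keeps only
the w highest-scoring unions as the next beam.  A union that would not grow
the subset, or whose accuracy was already computed on another path (a
"closed node"), is marked with a negative sentinel and never re-evaluated.
The search stops when the best accuracy reaches ``acc_max``, when ``depth``
layers have been built, or (optionally) when the layer-to-layer accuracy
gain falls below ``delta``.  The surviving subsets of the final layer are
the optimal subsets A*: minimum-size subsets with maximal training
accuracy.

One fixed CV partition per run: every cell of every layer is scored against
the same folds, so the per-layer accuracy trace is comparable across
layers.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from genebeam.classify_eval import (
    ClassifierSpec,
    FullFoldResult,
    cv_accuracy,
    full_fold_cv,
    stratified_folds,
)
from genebeam.io_norm import ExpressionDataset
from genebeam.prefilter import GeneRanking, preselect

__all__ = [
    "GeneSubset",
    "SearchConfig",
    "SearchState",
    "OptimalSubsets",
    "SubsetFilter",
    "expand",
    "beam_search",
    "multi_run_beam_search",
    "filter_subsets",
    "write_subsets_jsonl",
    "read_subsets_jsonl",
]

logger = logging.getLogger(__name__)

#: CM marker for closed or non-growing cells.  Negative so it can never
#: collide with a genuinely zero-accuracy open subset.
SENTINEL = -1.0


@dataclass(frozen=True)
class GeneSubset:
    """A candidate gene subset T with its training accuracy Acc(T)."""

    genes: tuple[str, ...]
    acc: float
    fullfold: FullFoldResult | None = None

    def __post_init__(self) -> None:
        genes = tuple(sorted(self.genes))
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in subset")
        object.__setattr__(self, "genes", genes)
        if not 0.0 <= self.acc <= 1.0:
            raise ValueError("accuracy outside [0, 1]")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SearchConfig:
    """Beam-search parameters.

    Parameters
    ----------
    p : int
        Number of pre-selected candidate genes.
    w : int
        Beam width: subsets kept per layer.  Layer 1 always keeps all p
        singletons regardless of w.  ``w_schedule`` optionally overrides w
        per layer (entry t applies to layer t + 2, the first expanded
        layer).
    acc_max : float in (0, 1]
        Stop as soon as a layer reaches this accuracy.
        ``acc_max_schedule`` optionally sets a per-layer threshold instead.
    depth : int
        Maximum number of layers, i.e. the largest subset size explored.
    delta : float or None
        Optional plateau stop: end when the layer-to-layer gain in best
        accuracy falls below delta.  Off by default.
    tau : float or None
        Optional final filter: keep only final-layer subsets within tau of
        the best accuracy.  None keeps all top-w survivors.
    normalize_per_fold : bool
        Z-score each restricted column block on fold-training statistics
        before scoring.  Off by default; the conventional pipeline
        normalizes the whole training set once before the search.
    """

    p: int
    w: int
    acc_max: float = 1.0
    depth: int = 10
    delta: float | None = None
    tau: float | None = None
    normalize_per_fold: bool = False
    w_schedule: tuple[int, ...] | None = None
    acc_max_schedule: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be positive")
        if self.w < 1:
            raise ValueError("beam width w must be at least 1")
        if not 0.0 < self.acc_max <= 1.0:
            raise ValueError("acc_max must lie in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.w_schedule is not None:
            object.__setattr__(self, "w_schedule", tuple(self.w_schedule))
        if self.acc_max_schedule is not None:
            object.__setattr__(
                self, "acc_max_schedule", tuple(self.acc_max_schedule)
            )

    def width_at(self, layer: int) -> int:
        """Beam width for the given expanded layer (layer >= 2)."""
        if self.w_schedule:
            idx = min(layer - 2, len(self.w_schedule) - 1)
            return self.w_schedule[idx]
        return self.w

    def acc_max_at(self, layer: int) -> float:
        if self.acc_max_schedule:
            idx = min(layer - 2, len(self.acc_max_schedule) - 1)
            return self.acc_max_schedule[idx]
        return self.acc_max


@dataclass
class SearchState:
    """Mutable search bookkeeping: beam rows, candidate columns, the
    classification matrix of the last layer, the closed-node registry, the
    per-layer best-accuracy trace, and the Acc(T) call counter."""

    rows: list[GeneSubset]
    columns: tuple[str, ...]
    cm: np.ndarray | None
    seen: dict[tuple[str, ...], float]
    trace: list[float]
    evaluations: int
    layer: int


@dataclass(frozen=True)
class OptimalSubsets:
    """The optimal subsets A* of one search run."""

    subsets: tuple[GeneSubset, ...]
    run_id: int
    trace: tuple[float, ...] = ()
    evaluations: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "subsets", tuple(self.subsets))
        object.__setattr__(self, "trace", tuple(self.trace))

    @property
    def union_genes(self) -> set[str]:
        """All genes appearing in any optimal subset."""
        return set(itertools.chain.from_iterable(s.genes for s in self.subsets))

    def __len__(self) -> int:
        return len(self.subsets)

    def __iter__(self):
        return iter(self.subsets)


def _rank_key(ranking: GeneRanking | None):
    """Deterministic ordering of candidate subsets: accuracy descending,
    then the sum of members' KWRST ranks ascending (stronger marginal genes
    first), then the canonical gene tuple."""
    if ranking is None:
        def key(item):
            genes, acc = item
            return (-acc, genes)
    else:
        ranks = {g: r for r, g in enumerate(
            ranking.gene_ids[j] for j in ranking.order
        )}

        def key(item):
            genes, acc = item
            return (-acc, sum(ranks.get(g, len(ranks)) for g in genes), genes)
    return key


def _evaluate(
    state: SearchState,
    genes: tuple[str, ...],
    ds: ExpressionDataset,
    spec: ClassifierSpec,
    folds,
    normalize_per_fold: bool,
) -> float:
    acc = cv_accuracy(
        ds, genes, spec, folds=folds, normalize_per_fold=normalize_per_fold
    )
    state.seen[genes] = acc
    state.evaluations += 1
    return acc


def expand(
    state: SearchState,
    ds: ExpressionDataset,
    spec: ClassifierSpec,
    folds=None,
    ranking: GeneRanking | None = None,
    config: SearchConfig | None = None,
) -> SearchState:
    """Score the classification matrix for the current beam and advance one
    layer.

    Cell (i, j) holds Acc(Row[i] union Column[j]); a cell whose column gene
    is already in the row subset, or whose union was evaluated before,
    carries the sentinel.  On the first expansion the beam consists of the
    p singletons, the matrix is symmetric, and only the lower triangle is
    evaluated and mirrored.  The open cells are ranked and the top w unions
    become the next beam.
    """
    if not state.rows:
        raise ValueError("beam is empty")
    if config is None:
        config = SearchConfig(p=len(state.columns), w=len(state.rows))
    if folds is None:
        folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
    n_rows, p = len(state.rows), len(state.columns)
    cm = np.full((n_rows, p), SENTINEL)
    candidates: list[tuple[tuple[str, ...], float]] = []
    first = (
        state.layer == 1
        and n_rows == p
        and all(
            s.genes == (state.columns[i],) for i, s in enumerate(state.rows)
        )
    )

    def open_cell(i: int, j: int) -> None:
        row, col = state.rows[i], state.columns[j]
        if col in row.genes:
            return
        union = tuple(sorted(row.genes + (col,)))
        if union in state.seen:
            return
        acc = _evaluate(
            state, union, ds, spec, folds, config.normalize_per_fold
        )
        cm[i, j] = acc
        candidates.append((union, acc))

    if first:
        for i in range(n_rows):
            for j in range(i):
                open_cell(i, j)
                cm[j, i] = cm[i, j]
    else:
        for i in range(n_rows):
            for j in range(p):
                open_cell(i, j)

    next_layer = state.layer + 1
    if not candidates:
        logger.info("layer %d: beam exhausted, no open cells", next_layer)
        return state
    candidates.sort(key=_rank_key(ranking))
    width = config.width_at(next_layer)
    new_rows = [GeneSubset(genes=g, acc=a) for g, a in candidates[:width]]
    best = candidates[0][1]
    if state.trace and best < state.trace[-1]:
        # growing every beam subset can hurt CV accuracy; worth surfacing
        logger.warning(
            "layer %d best accuracy %.4f fell below layer %d's %.4f",
            next_layer, best, state.layer, state.trace[-1],
        )
    state.rows = new_rows
    state.cm = cm
    state.trace.append(best)
    state.layer = next_layer
    logger.info(
        "layer %d: best accuracy %.4f, %d open cells, beam %d",
        next_layer, best, len(candidates), len(new_rows),
    )
    return state


def beam_search(
    ds: ExpressionDataset,
    ranking: GeneRanking,
    config: SearchConfig,
    spec: ClassifierSpec,
) -> OptimalSubsets:
    """Run the full beam search and return the optimal subsets A*.

    Layer 1 scores all p pre-selected singletons (the beam always keeps all
    p of them there).  Expansion proceeds until the stopping accuracy, the
    depth bound, or the optional accuracy plateau is reached; the top-w
    subsets of the final layer form A*.  Only training data may be passed:
    the search must never see the test set.
    """
    if config.p > ds.n:
        raise ValueError(f"p={config.p} exceeds the {ds.n} genes available")
    genes = preselect(ranking, config.p)
    folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
    state = SearchState(
        rows=[], columns=tuple(genes), cm=None, seen={}, trace=[],
        evaluations=0, layer=1,
    )
    # layer 1 keeps all p singletons, in column order so the first CM is
    # symmetric and only its lower triangle needs evaluating
    singles = [
        ((g,), _evaluate(state, (g,), ds, spec, folds,
                         config.normalize_per_fold))
        for g in genes
    ]
    state.rows = [GeneSubset(genes=g, acc=a) for g, a in singles]
    best1 = max(a for _, a in singles)
    state.trace.append(best1)
    logger.info("layer 1: best single-gene accuracy %.4f", best1)

    while state.layer < config.depth:
        prev_layer = state.layer
        expand(state, ds, spec, folds=folds, ranking=ranking, config=config)
        if state.layer == prev_layer:  # beam exhausted
            break
        if state.trace[-1] >= config.acc_max_at(state.layer):
            break
        if (
            config.delta is not None
            and len(state.trace) >= 2
            and abs(state.trace[-1] - state.trace[-2]) < config.delta
        ):
            break

    if state.layer == 1:
        # no expansion happened: A* is the top-w singletons by accuracy
        ranked = sorted(
            ((s.genes, s.acc) for s in state.rows), key=_rank_key(ranking)
        )
        final = [GeneSubset(genes=g, acc=a) for g, a in ranked[: config.w]]
    else:
        final = list(state.rows)
    if config.tau is not None and final:
        best = max(s.acc for s in final)
        final = [s for s in final if s.acc >= best - config.tau]
    return OptimalSubsets(
        subsets=tuple(final),
        run_id=spec.seed,
        trace=tuple(state.trace),
        evaluations=state.evaluations,
    )


def multi_run_beam_search(
    ds: ExpressionDataset,
    ranking: GeneRanking,
    config: SearchConfig,
    spec: ClassifierSpec,
    seeds,
) -> list[OptimalSubsets]:
    """One search run per seed, each with an independent CV partition.

    The KNN-wrapped search is sensitive to the fold partition, so it is
    conventionally run several times (five in the classic setup) and the
    runs' subsets pooled; a deterministic-partition classifier needs only
    one run.
    """
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: identical runs will be produced")
    return [
        beam_search(ds, ranking, config, replace(spec, seed=s))
        for s in seeds
    ]


@dataclass(frozen=True)
class SubsetFilter:
    """Conjunction of predicates over A*: 10-fold accuracy bounds,
    Full-fold mean bounds, and a top-n cut.  Accuracy values are fractions
    in [0, 1]."""

    tenfold_min: float | None = None
    tenfold_eq: float | None = None
    fullfold_min: float | None = None
    fullfold_eq: float | None = None
    top_n: int | None = None

    _EQ_TOL = 1e-9

    @classmethod
    def parse(cls, text: str) -> "SubsetFilter":
        """Parse e.g. ``"tenfold>=1.0,fullfold>=0.99,top=300"``."""
        kwargs: dict[str, float | int] = {}
        for clause in filter(None, (c.strip() for c in text.split(","))):
            for name, ge_key, eq_key in (
                ("tenfold", "tenfold_min", "tenfold_eq"),
                ("fullfold", "fullfold_min", "fullfold_eq"),
            ):
                if clause.startswith(name):
                    rest = clause[len(name):]
                    if rest.startswith(">="):
                        kwargs[ge_key] = float(rest[2:])
                    elif rest.startswith("="):
                        kwargs[eq_key] = float(rest.lstrip("=") or "nan")
                    else:
                        raise ValueError(f"cannot parse clause {clause!r}")
                    break
            else:
                if clause.startswith("top"):
                    kwargs["top_n"] = int(clause.split("=", 1)[1])
                else:
                    raise ValueError(f"unknown filter clause {clause!r}")
        return cls(**kwargs)

    def needs_fullfold(self) -> bool:
        return self.fullfold_min is not None or self.fullfold_eq is not None


def filter_subsets(
    optimal: OptimalSubsets,
    criterion: SubsetFilter,
    ds: ExpressionDataset | None = None,
    spec: ClassifierSpec | None = None,
) -> OptimalSubsets:
    """Apply a SubsetFilter to A*, preserving order.

    Full-fold clauses trigger lazy Full-fold CV computation for subsets
    that do not carry one yet (requires ``ds`` and ``spec``).  An empty
    result is returned with a warning rather than raised.
    """
    subsets = list(optimal.subsets)
    if criterion.needs_fullfold():
        if ds is None or spec is None:
            raise ValueError(
                "fullfold clauses need the dataset and classifier spec"
            )
        subsets = [
            s if s.fullfold is not None
            else replace(s, fullfold=full_fold_cv(ds, s, spec))
            for s in subsets
        ]
    tol = SubsetFilter._EQ_TOL

    def keep(s: GeneSubset) -> bool:
        if criterion.tenfold_min is not None and s.acc < criterion.tenfold_min:
            return False
        if (
            criterion.tenfold_eq is not None
            and abs(s.acc - criterion.tenfold_eq) > tol
        ):
            return False
        if criterion.fullfold_min is not None:
            if s.fullfold is None or s.fullfold.mean < criterion.fullfold_min:
                return False
        if criterion.fullfold_eq is not None:
            if s.fullfold is None or (
                abs(s.fullfold.mean - criterion.fullfold_eq) > tol
            ):
                return False
        return True

    kept = [s for s in subsets if keep(s)]
    if criterion.top_n is not None:
        kept = kept[: criterion.top_n]
    if not kept:
        warnings.warn("subset filter left no subsets")
    return replace(optimal, subsets=tuple(kept))


def write_subsets_jsonl(runs, path) -> None:
    """Write one JSON record per subset: genes, size, 10-fold accuracy,
    Full-fold mean/std when available, and the run id."""
    runs = [runs] if isinstance(runs, OptimalSubsets) else list(runs)
    with open(path, "w", encoding="utf-8") as fh:
        for run in runs:
            for s in run.subsets:
                rec = {
                    "genes": list(s.genes),
                    "size": s.size,
                    "tenfold_acc": s.acc,
                    "fullfold_mean": (
                        s.fullfold.mean if s.fullfold else None
                    ),
                    "fullfold_std": s.fullfold.std if s.fullfold else None,
                    "run_id": run.run_id,
                }
                fh.write(json.dumps(rec) + "\n")


def read_subsets_jsonl(path) -> list[OptimalSubsets]:
    """Read subset records back, grouping them into one OptimalSubsets per
    run id (Full-fold summaries are not reconstructed)."""
    by_run: dict[int, list[GeneSubset]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            by_run.setdefault(rec["run_id"], []).append(
                GeneSubset(
                    genes=tuple(rec["genes"]), acc=rec["tenfold_acc"]
                )
            )
    return [
        OptimalSubsets(subsets=tuple(subs), run_id=rid)
        for rid, subs in by_run.items()
    ]
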