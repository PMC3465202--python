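from itertools import combinations

import numpy as np
import pytest

from genebeam.classify_eval import ClassifierSpec, cv_accuracy, stratified_folds
from genebeam.io_norm import zscore_normalize
from genebeam.prefilter import kwrst_pvalues
from genebeam.search import (
    GeneSubset,
    OptimalSubsets,
    SearchConfig,
    SearchState,
    SubsetFilter,
    beam_search,
    expand,
    filter_subsets,
    multi_run_beam_search,
    read_subsets_jsonl,
    write_subsets_jsonl,
)


def _setup(sim, seed=0, folds=10):
    ds = zscore_normalize(sim.dataset)
    ranking = kwrst_pvalues(ds)
    spec = ClassifierSpec(kind="knn", cv_folds=folds, seed=seed)
    return ds, ranking, spec


class TestExpand:
    def test_first_expansion_equals_exhaustive_pair_scoring(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        p, w = 5, 10
        cfg = SearchConfig(p=p, w=w, depth=2)
        genes = [ranking.gene_ids[j] for j in ranking.order[:p]]
        folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
        state = SearchState(
            rows=[GeneSubset(genes=(g,), acc=cv_accuracy(ds, (g,), spec,
                                                         folds=folds))
                  for g in genes],
            columns=tuple(genes), cm=None,
            seen={(g,): 0.0 for g in genes}, trace=[], evaluations=0,
            layer=1,
        )
        expand(state, ds, spec, folds=folds, ranking=ranking, config=cfg)
        # oracle: score all C(5,2) unordered pairs directly
        oracle = {
            tuple(sorted(pair)): cv_accuracy(ds, pair, spec, folds=folds)
            for pair in combinations(genes, 2)
        }
        got = {s.genes: s.acc for s in state.rows}
        assert got == oracle
        assert state.evaluations == len(oracle)

    def test_closed_nodes_never_reevaluated(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=6, w=30, depth=4)
        opt = beam_search(ds, ranking, cfg, spec)
        # the registry is the set of evaluated subsets: counts must agree
        assert opt.evaluations <= cfg.depth * max(cfg.p, cfg.w) * cfg.p

    def test_empty_beam_is_error(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        state = SearchState(
            rows=[], columns=("g0001",), cm=None, seen={}, trace=[],
            evaluations=0, layer=1,
        )
        with pytest.raises(ValueError, match="empty"):
            expand(state, ds, spec)


class TestBeamSearch:
    def test_depth_one_returns_top_singletons(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=8, w=3, depth=1)
        opt = beam_search(ds, ranking, cfg, spec)
        assert all(s.size == 1 for s in opt.subsets)
        genes = [ranking.gene_ids[j] for j in ranking.order[:8]]
        folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
        singles = sorted(
            (cv_accuracy(ds, (g,), spec, folds=folds) for g in genes),
            reverse=True,
        )
        got = sorted((s.acc for s in opt.subsets), reverse=True)
        assert got == singles[:3]

    def test_separable_pair_stops_at_size_two(self, separable_dataset):
        ds = zscore_normalize(separable_dataset)
        ranking = kwrst_pvalues(ds)
        spec = ClassifierSpec(kind="knn", cv_folds=10, seed=0)
        cfg = SearchConfig(p=6, w=10, acc_max=1.0, depth=6)
        opt = beam_search(ds, ranking, cfg, spec)
        assert all(s.size == 2 for s in opt.subsets)
        best = max(opt.subsets, key=lambda s: s.acc)
        assert best.acc == 1.0
        # verify the winning pair by direct CV
        folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
        assert cv_accuracy(ds, best.genes, spec, folds=folds) == 1.0

    def test_matches_exhaustive_search_at_full_width(self, weak_sim):
        # w >= C(p, 3) makes the beam lossless: layer-3 accuracies must
        # equal exhaustive enumeration of all 3-gene subsets
        ds, ranking, spec = _setup(weak_sim)
        p, depth = 6, 3
        w = len(list(combinations(range(p), depth)))
        cfg = SearchConfig(p=p, w=w, depth=depth)
        opt = beam_search(ds, ranking, cfg, spec)
        assert all(s.size == depth for s in opt.subsets)
        genes = [ranking.gene_ids[j] for j in ranking.order[:p]]
        folds = stratified_folds(ds.labels, spec.cv_folds, spec.seed)
        oracle = sorted(
            cv_accuracy(ds, trip, spec, folds=folds)
            for trip in combinations(genes, 3)
        )
        assert sorted(s.acc for s in opt.subsets) == oracle

    def test_subset_growth_one_gene_per_layer(self, weak_sim):
        ds, ranking, spec = _setup(weak_sim)
        cfg = SearchConfig(p=6, w=5, depth=4)
        opt = beam_search(ds, ranking, cfg, spec)
        assert all(s.size == 4 for s in opt.subsets)
        assert len(opt.trace) == 4

    def test_evaluation_budget(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=10, w=7, depth=3)
        opt = beam_search(ds, ranking, cfg, spec)
        assert opt.evaluations <= cfg.depth * max(cfg.w, cfg.p) * cfg.p

    def test_p_exceeding_n_is_error(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        with pytest.raises(ValueError):
            beam_search(
                ds, ranking, SearchConfig(p=ds.n + 1, w=5, depth=2), spec
            )

    def test_delta_plateau_stops_early(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=6, w=5, depth=6, delta=1.0)
        opt = beam_search(ds, ranking, cfg, spec)
        # any gain below delta=1 triggers the plateau stop at layer 2
        assert all(s.size == 2 for s in opt.subsets)


class TestMultiRun:
    def test_same_seed_reproduces_exactly(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=6, w=5, depth=3)
        with pytest.warns(UserWarning, match="duplicate seeds"):
            runs = multi_run_beam_search(ds, ranking, cfg, spec, [3, 3])
        assert runs[0].subsets == runs[1].subsets

    def test_each_run_within_beam_width(self, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=6, w=4, depth=3)
        runs = multi_run_beam_search(ds, ranking, cfg, spec, [1, 2, 3])
        assert all(len(r) <= 4 for r in runs)
        assert [r.run_id for r in runs] == [1, 2, 3]


class TestFilterSubsets:
    def _opt(self, gene_ids=("a", "b", "c")):
        a, b, c = gene_ids[:3]
        return OptimalSubsets(
            subsets=(
                GeneSubset(genes=(a, b), acc=1.0),
                GeneSubset(genes=(a, c), acc=0.95),
                GeneSubset(genes=(b, c), acc=1.0),
            ),
            run_id=0,
        )

    def test_top_n_larger_than_set_is_identity(self):
        out = filter_subsets(self._opt(), SubsetFilter(top_n=300))
        assert out.subsets == self._opt().subsets

    def test_tenfold_equality_keeps_exact_matches(self):
        opt = self._opt()
        out = filter_subsets(opt, SubsetFilter(tenfold_eq=1.0))
        assert out.subsets == (opt.subsets[0], opt.subsets[2])

    def test_conjunction_equals_intersection_of_predicates(self, planted_sim):
        ds, _, spec = _setup(planted_sim, folds=5)
        opt = self._opt(ds.gene_ids)
        crit = SubsetFilter(tenfold_min=1.0, fullfold_min=0.5)
        both = filter_subsets(opt, crit, ds=ds, spec=spec)
        only_ten = filter_subsets(opt, SubsetFilter(tenfold_min=1.0))
        only_ff = filter_subsets(
            opt, SubsetFilter(fullfold_min=0.5), ds=ds, spec=spec
        )
        expected = {s.genes for s in only_ten} & {
            s.genes for s in only_ff
        }
        assert {s.genes for s in both} == expected

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="no subsets"):
            out = filter_subsets(self._opt(), SubsetFilter(tenfold_min=1.1))
        assert out.subsets == ()

    def test_parse_round_trip(self):
        crit = SubsetFilter.parse("tenfold>=1.0,fullfold>=0.99,top=300")
        assert crit == SubsetFilter(
            tenfold_min=1.0, fullfold_min=0.99, top_n=300
        )


class TestJsonl:
    def test_round_trip(self, tmp_path, planted_sim):
        ds, ranking, spec = _setup(planted_sim)
        cfg = SearchConfig(p=5, w=4, depth=2)
        runs = multi_run_beam_search(ds, ranking, cfg, spec, [0, 1])
        path = tmp_path / "subsets.jsonl"
        write_subsets_jsonl(runs, path)
        back = read_subsets_jsonl(path)
        assert [
            [(s.genes, s.acc) for s in r.subsets] for r in back
        ] == [[(s.genes, s.acc) for s in r.subsets] for r in runs]
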