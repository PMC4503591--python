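import numpy as np
import pytest
from scipy import stats

from nichegen import enm
from nichegen.enm import (
    LabelledRecords,
    ModelEvaluation,
    binomial_deviance,
    build_provider,
    mahalanobis_suitability,
    sample_pseudoabsences,
    select_top_combos,
    split_records,
    standardize,
    tss,
    tune_learner,
)
from nichegen.grids import GridSpec, RasterStack
from nichegen.learners import LearnerSpec, fit_learner, predict_proba


class TestStandardize:
    def test_moments_and_shift_invariance(self, env_stack):
        std, sz = standardize(env_stack)
        for name in std.names:
            assert std[name].mean() == pytest.approx(0.0, abs=1e-9)
            assert std[name].std() == pytest.approx(1.0, abs=1e-9)
        shifted = env_stack.copy()
        shifted.layers["sst"] = shifted.layers["sst"] + 100.0
        std2, _ = standardize(shifted)
        np.testing.assert_allclose(std2["sst"], std["sst"], atol=1e-9)

    def test_population_convention_two_cells(self):
        grid = GridSpec(0, 0, 1.0, 2, 1)
        stack = RasterStack(grid, {"x": np.array([[0.0, 2.0]]),
                                   "y": np.array([[1.0, 3.0]])})
        std, _ = standardize(stack)
        np.testing.assert_allclose(std["x"], [[-1.0, 1.0]])

    def test_zero_variance_raises(self, constant_stack):
        with pytest.raises(ValueError):
            standardize(constant_stack)

    def test_transform_reapplies_to_projection_stack(self, env_stack):
        _, sz = standardize(env_stack)
        future = env_stack.copy()
        future.layers["sst"] = future.layers["sst"] + 2.0
        std_future = sz.transform_stack(future)
        # same frame: warming shows up as a positive standardized shift
        assert std_future["sst"].mean() == pytest.approx(
            2.0 / sz.sds[list(sz.names).index("sst")], abs=1e-9
        )


class TestMahalanobis:
    def test_centroid_has_suitability_one(self):
        grid = GridSpec(0, 0, 1.0, 3, 1)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        stack = RasterStack(grid, {"a": np.zeros((1, 3)), "b": np.zeros((1, 3))})
        suit = mahalanobis_suitability(X, stack)
        np.testing.assert_allclose(suit, 1.0)

    def test_univariate_tail_matches_chi2(self):
        rng = np.random.default_rng(0)
        pres = rng.normal(0.0, 1.0, size=(200, 1))
        mu, sd = pres.mean(), pres.std(ddof=1)
        grid = GridSpec(0, 0, 1.0, 1, 1)
        stack = RasterStack(grid, {"a": np.array([[mu + 1.96 * sd]])})
        suit = mahalanobis_suitability(pres, stack)
        assert suit[0, 0] == pytest.approx(0.05, abs=1e-3)

    def test_matches_explicit_quadratic_form(self):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.5], [3.0, 1.0], [1.5, 2.0]])
        mu = X.mean(axis=0)
        S = np.cov(X, rowvar=False)
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        S_inv = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        cell = np.array([2.5, 0.5])
        d = cell - mu
        d2 = d @ S_inv @ d
        grid = GridSpec(0, 0, 1.0, 1, 1)
        stack = RasterStack(grid, {"a": np.array([[cell[0]]]), "b": np.array([[cell[1]]])})
        suit = mahalanobis_suitability(X, stack)
        assert suit[0, 0] == pytest.approx(stats.chi2.sf(d2, df=2))

    def test_too_few_presences_raises(self):
        grid = GridSpec(0, 0, 1.0, 1, 1)
        stack = RasterStack(grid, {"a": np.zeros((1, 1)), "b": np.zeros((1, 1))})
        with pytest.raises(ValueError):
            mahalanobis_suitability(np.zeros((2, 2)), stack)


class TestPseudoAbsences:
    def test_contract_audited_over_seeds(self, env_stack, occurrences):
        provider, _ = build_provider(env_stack, occurrences)
        n = len(provider.presence_cells)
        flat = provider.surface.ravel()
        for seed in range(20):
            cells = sample_pseudoabsences(
                provider.surface, n, provider.presence_cells,
                np.random.default_rng(seed),
            )
            assert len(cells) == n
            assert (flat[cells] <= 0.2).all()
            assert not np.intersect1d(cells, provider.presence_cells).size

    def test_exact_eligible_set_taken(self):
        surface = np.array([[0.1, 0.15, 0.9], [0.95, 0.05, 0.99]])
        cells = sample_pseudoabsences(
            surface, 3, np.array([], dtype=int), np.random.default_rng(0)
        )
        assert set(cells) == {0, 1, 4}

    def test_shortfall_error_names_counts(self):
        surface = np.array([[0.1, 0.9]])
        with pytest.raises(ValueError, match="only 1"):
            sample_pseudoabsences(surface, 2, np.array([], dtype=int),
                                  np.random.default_rng(0))

    def test_seed_reproducibility(self, env_stack, occurrences):
        provider, _ = build_provider(env_stack, occurrences)
        n = len(provider.presence_cells)
        a = sample_pseudoabsences(provider.surface, n, provider.presence_cells,
                                  np.random.default_rng(42))
        b = sample_pseudoabsences(provider.surface, n, provider.presence_cells,
                                  np.random.default_rng(42))
        c = sample_pseudoabsences(provider.surface, n, provider.presence_cells,
                                  np.random.default_rng(43))
        np.testing.assert_array_equal(a, b)
        assert set(a) != set(c)


def _toy_records(n_per_class=100, p=2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, p))
    y = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return LabelledRecords(X=X, y=y, cells=np.arange(2 * n_per_class),
                           predictors=tuple(f"p{i}" for i in range(p)))


class TestSplitRecords:
    def test_seventy_thirty_stratified_disjoint(self):
        records = _toy_records(100)
        train, test = split_records(records, np.random.default_rng(0))
        assert len(train) == 140 and len(test) == 60
        assert records.y[train].sum() == 70
        assert records.y[test].sum() == 30
        assert not np.intersect1d(train, test).size
        assert len(np.union1d(train, test)) == 200

    def test_stratification_within_one_record(self):
        records = _toy_records(17)
        train, _ = split_records(records, np.random.default_rng(1))
        per_class = np.bincount(records.y[train])
        assert abs(per_class[0] - per_class[1]) <= 1

    def test_too_small_raises(self):
        small = _toy_records(4)  # 8 records total
        with pytest.raises(ValueError):
            split_records(small, np.random.default_rng(0))


class TestTuneLearner:
    def test_singleton_grid_chosen(self):
        records = _toy_records(30)
        spec = LearnerSpec("spline", ({"degree": 1},))
        _, params = tune_learner(records.X, records.y, spec, k=5, seed=0)
        assert params == {"degree": 1}

    def test_separable_data_low_deviance(self):
        n = 60
        X = np.concatenate([np.zeros((n, 1)), np.ones((n, 1))]) + \
            np.random.default_rng(0).normal(0, 0.01, size=(2 * n, 1))
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        spec = LearnerSpec("brt", ({"n_trees": 100, "tree_complexity": 1,
                                    "learning_rate": 0.05},))
        model, _ = tune_learner(X, y, spec, k=5, seed=0)
        dev = binomial_deviance(y, predict_proba(model, X))
        assert dev / len(y) < 0.1

    def test_deviance_matches_hand_formula(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.9, 0.2, 0.6, 0.4])
        expected = -2 * (
            np.log(0.9) + np.log(0.8) + np.log(0.6) + np.log(0.6)
        )
        assert binomial_deviance(y, p) == pytest.approx(expected)

    def test_single_class_raises(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError):
            tune_learner(X, np.ones(10, int), LearnerSpec("spline", ({"degree": 1},)))


class TestTSS:
    def test_perfect_ranking(self):
        t, thr, sens, spec = tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert t == pytest.approx(1.0)
        assert sens == 1.0 and spec == 1.0

    def test_uninformative_scores(self):
        t, *_ = tss([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert t == pytest.approx(0.0)

    def test_confusion_arithmetic(self):
        # TP=8, FN=2, TN=6, FP=4 at threshold 0.5
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 6 + [0.8] * 4)
        labels = np.array([1] * 10 + [0] * 10)
        t, thr, sens, spec = tss(scores, labels)
        # the sweep will find the best threshold; force evaluation at 0.5
        pred = scores >= 0.5
        sens05 = (pred[:10]).sum() / 10
        spec05 = (~pred[10:]).sum() / 10
        assert sens05 == pytest.approx(0.8)
        assert spec05 == pytest.approx(0.6)
        assert sens05 + spec05 - 1 == pytest.approx(0.4)
        assert t >= 0.4  # the maximizing threshold can only do better

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            tss([0.1, 0.9], [1, 1])

    def test_matches_brute_force_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 51)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)
            t, thr, _, _ = tss(scores, labels)
            best = -np.inf
            best_thr = None
            for cand in sorted(set(scores) | {0.0, 1.0}):
                pred = scores >= cand
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                if sens + spec - 1 > best + 1e-12:
                    best, best_thr = sens + spec - 1, cand
            assert t == pytest.approx(best)
            assert thr == pytest.approx(best_thr)


class TestSelectTopCombos:
    @staticmethod
    def _ev(name, values):
        values = np.asarray(values, dtype=float)
        return ModelEvaluation(combo=(name,), family="brt", tss_values=values,
                               thresholds=np.full(len(values), 0.5))

    def test_identical_vectors_both_selected(self):
        v = np.linspace(0.5, 0.7, 20)
        sel = select_top_combos([self._ev("a", v), self._ev("b", v.copy())])
        assert {e.combo for e in sel} == {("a",), ("b",)}

    def test_clearly_worse_combo_rejected(self):
        rng = np.random.default_rng(0)
        good = 0.8 + rng.normal(0, 0.02, 50)
        bad = good - 0.3
        sel = select_top_combos([self._ev("good", good), self._ev("bad", bad)])
        assert [e.combo for e in sel] == [("good",)]

    def test_null_distribution_keeps_several(self):
        rng = np.random.default_rng(1)
        evs = [self._ev(f"c{i}", 0.6 + rng.normal(0, 0.05, 50)) for i in range(20)]
        sel = select_top_combos(evs)
        assert len(sel) >= 2

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        evs = [self._ev(f"c{i}", 0.6 + rng.normal(0, 0.05, 50)) for i in range(8)]
        sel1 = select_top_combos(list(evs))
        sel2 = select_top_combos(list(reversed(evs)))
        assert [e.combo for e in sel1] == [e.combo for e in sel2]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            select_top_combos([self._ev("a", [0.5, 0.6])])
        with pytest.raises(ValueError):
            select_top_combos([self._ev("a", [0.5]), self._ev("b", [0.6])])


class TestEvaluateCombination:
    def test_single_repeat_deterministic(self, env_stack, occurrences):
        provider, _ = build_provider(env_stack, occurrences)
        spec = LearnerSpec("spline", ({"degree": 1},))
        e1 = enm.evaluate_combination(("sst",), spec, provider, repeats=1, seed=3, k=5)
        e2 = enm.evaluate_combination(("sst",), spec, provider, repeats=1, seed=3, k=5)
        assert e1.tss_values[0] == e2.tss_values[0]
        assert len(e1.tss_values) == 1

    def test_null_noise_combination_tss_near_zero(self):
        # a proper null: spatially unstructured (iid) noise predictors, and a
        # pseudo-absence surface built from the truth predictors only, so the
        # labels are exchangeable with respect to the evaluated features.
        # (spatially smoothed noise would confound with the species' spatial
        # clustering and inflate the null)
        from nichegen.synthetic import (
            NicheResponse, PredictorSpec, VirtualNiche, make_env_grids,
            sample_occurrences, virtual_suitability,
        )

        specs = [
            PredictorSpec("sst", slope=-0.5, noise_sd=0.6, smoothing_length=2),
            PredictorSpec("airt", slope=-0.7, noise_sd=0.8, smoothing_length=2),
            PredictorSpec("wn1", slope=0.0, noise_sd=1.0, smoothing_length=0),
            PredictorSpec("wn2", slope=0.0, noise_sd=1.0, smoothing_length=0),
        ]
        stack = make_env_grids((-30, 30, 30, 70), 1.0, specs, seed=11)
        niche = VirtualNiche(
            {"sst": NicheResponse(-25.0, 3.0), "airt": NicheResponse(-35.0, 4.0)},
            truth_threshold=0.3,
        )
        truth = virtual_suitability(stack, niche)
        occ = sample_occurrences(truth, stack.grid, 150, seed=7, truth_threshold=0.3)
        provider, _ = build_provider(stack, occ, surface_predictors=["sst", "airt"])
        spec = LearnerSpec("spline", ({"degree": 1},))
        ev = enm.evaluate_combination(("wn1", "wn2"), spec, provider,
                                      repeats=20, seed=23, k=5)
        assert abs(ev.mean_tss) < 0.15


class TestPredictorImportance:
    @staticmethod
    def _ev(combo, mean):
        return ModelEvaluation(combo=combo, family="brt",
                               tss_values=np.full(5, mean),
                               thresholds=np.full(5, 0.5))

    def test_alone_and_gain(self):
        evs = [
            self._ev(("a",), 0.5),
            self._ev(("b",), 0.2),
            self._ev(("a", "b"), 0.6),
        ]
        imp = enm.predictor_importance(evs)
        assert imp.loc["a", "tss_alone"] == pytest.approx(0.5)
        assert imp.loc["a", "mean_gain"] == pytest.approx(0.4)  # 0.6 - 0.2
        assert imp.loc["b", "mean_gain"] == pytest.approx(0.1)  # 0.6 - 0.5

    def test_gain_undefined_without_pairs(self):
        evs = [self._ev(("a",), 0.5), self._ev(("b",), 0.2)]
        imp = enm.predictor_importance(evs)
        assert np.isnan(imp.loc["a", "mean_gain"])

    def test_missing_singleton_raises(self):
        with pytest.raises(ValueError):
            enm.predictor_importance([self._ev(("a", "b"), 0.6), self._ev(("a",), 0.5)])
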