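"""Combination enumeration, probability stacking, AdaBoost combiner,
best-combination selection, majority baseline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mspheno.compare import MetricSet
from mspheno.fusion import (
    Combination,
    EnsembleResult,
    enumerate_combinations,
    fit_combiner,
    majority_baseline,
    select_best,
    stack_probabilities,
)
from mspheno.models import BaseModelResult, FoldPlan


class TestEnumerateCombinations:
    def test_six_models_give_57(self):
        assert len(enumerate_combinations([f"s{i}" for i in range(6)])) == 57

    def test_seven_models_give_120(self):
        assert len(enumerate_combinations([f"s{i}" for i in range(7)])) == 120

    def test_two_models_give_single_pair(self):
        combos = enumerate_combinations(["a", "b"])
        assert combos == [Combination(("a", "b"))]

    @pytest.mark.parametrize("n", range(2, 9))
    def test_count_matches_bruteforce_formula(self, n):
        ids = [f"m{i}" for i in range(n)]
        combos = enumerate_combinations(ids)
        brute = [
            c
            for size in range(2, n + 1)
            for c in itertools.combinations(sorted(ids), size)
        ]
        assert len(combos) == 2**n - n - 1 == len(brute)
        assert [c.members for c in combos] == brute

    def test_order_is_deterministic_size_then_lexicographic(self):
        combos = enumerate_combinations(["c", "a", "b"])
        assert [c.members for c in combos] == [
            ("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c"),
        ]


def _base_result(model_id, samples, probs):
    oof = pd.DataFrame(
        {
            "participant_id": [s[0] for s in samples],
            "period_index": [s[1] for s in samples],
            "fold": 0,
            "probability": probs,
            "label": 0,
        }
    )
    return BaseModelResult(model_id=model_id, oof=oof)


class TestStackProbabilities:
    def test_width_equals_combination_size(self):
        samples = [("P1", 1), ("P1", 2), ("P2", 1)]
        base = {
            m: _base_result(m, samples, [0.1, 0.2, 0.3]) for m in ("a", "b", "c")
        }
        meta = stack_probabilities(Combination(("a", "b", "c")), base)
        assert meta.shape == (3, 3)
        assert list(meta.columns) == ["a", "b", "c"]

    def test_rows_are_member_intersection(self):
        base = {
            "a": _base_result("a", [("P1", 1), ("P2", 1)], [0.1, 0.2]),
            "b": _base_result("b", [("P2", 1), ("P3", 1)], [0.3, 0.4]),
        }
        meta = stack_probabilities(Combination(("a", "b")), base)
        assert list(meta.index) == [("P2", 1)]

    def test_empty_intersection_is_error(self):
        base = {
            "a": _base_result("a", [("P1", 1)], [0.1]),
            "b": _base_result("b", [("P2", 1)], [0.2]),
        }
        with pytest.raises(ValueError):
            stack_probabilities(Combination(("a", "b")), base)


def _meta_and_labels(n_pids=8, periods=5, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    rows, y = [], []
    for i in range(n_pids):
        for k in range(1, periods + 1):
            rows.append((f"P{i+1:03d}", k))
            y.append((i + k) % 2)
    idx = pd.MultiIndex.from_tuples(rows, names=["participant_id", "period_index"])
    y = pd.Series(y, index=idx, name="label")
    if informative:
        meta = pd.DataFrame(
            {"a": y.to_numpy().astype(float), "b": y.to_numpy().astype(float)}, index=idx
        )
    else:
        meta = pd.DataFrame({"a": np.full(len(y), 0.5), "b": np.full(len(y), 0.5)}, index=idx)
    plan = FoldPlan(
        folds=[[f"P{i+1:03d}" for i in range(j, n_pids, 2)] for j in range(2)], seed=0,
        group_size=4,
    )
    return meta, y, plan


class TestFitCombiner:
    def test_perfectly_informative_members_reach_full_accuracy(self):
        meta, y, plan = _meta_and_labels(informative=True)
        res = fit_combiner(meta, y, plan, n_estimators_grid=(10,), inner_splits=2)
        assert res.metrics.accuracy == 1.0

    def test_constant_members_score_near_majority(self):
        meta, y, plan = _meta_and_labels(informative=False, seed=1)
        res = fit_combiner(meta, y, plan, n_estimators_grid=(10,), inner_splits=2)
        majority = max(y.mean(), 1 - y.mean())
        n = len(y)
        band = 3 * np.sqrt(majority * (1 - majority) / n) + 1e-9
        assert res.metrics.accuracy <= majority + band

    def test_noise_member_does_not_wreck_informative_combination(self):
        accs = []
        for seed in range(5):
            meta, y, plan = _meta_and_labels(informative=True, seed=seed)
            rng = np.random.default_rng(seed)
            meta2 = meta.assign(noise=rng.random(len(meta)))
            res2 = fit_combiner(meta2, y, plan, n_estimators_grid=(10,), inner_splits=2)
            res1 = fit_combiner(meta, y, plan, n_estimators_grid=(10,), inner_splits=2)
            accs.append(res1.metrics.accuracy - res2.metrics.accuracy)
        assert np.mean(accs) < 0.05

    def test_deterministic_given_seed(self):
        meta, y, plan = _meta_and_labels(informative=False, seed=2)
        r1 = fit_combiner(meta, y, plan, n_estimators_grid=(10, 50), inner_splits=2, seed=3)
        r2 = fit_combiner(meta, y, plan, n_estimators_grid=(10, 50), inner_splits=2, seed=3)
        pd.testing.assert_frame_equal(r1.oof, r2.oof)


def _result_with(f1, members):
    metrics = MetricSet(accuracy=f1, f1=f1, precision=f1, recall=f1, n_samples=10)
    return EnsembleResult(Combination(members), pd.DataFrame(), {}, metrics)


class TestSelectBest:
    def test_unique_maximum_selected(self):
        results = {
            Combination(("a", "b")): _result_with(0.6, ("a", "b")),
            Combination(("a", "c")): _result_with(0.8, ("a", "c")),
        }
        assert select_best(results).members == ("a", "c")

    def test_tie_broken_by_fewer_members(self):
        results = {
            Combination(("a", "b", "c", "d", "e")): _result_with(0.7, ("a", "b", "c", "d", "e")),
            Combination(("a", "b", "c")): _result_with(0.7, ("a", "b", "c")),
        }
        assert select_best(results).members == ("a", "b", "c")

    def test_full_tie_gives_lexicographically_first_smallest(self):
        results = {
            Combination(m): _result_with(0.5, m)
            for m in [("b", "c"), ("a", "b"), ("a", "b", "c")]
        }
        assert select_best(results).members == ("a", "b")


class TestMajorityBaseline:
    def _labels(self, values, pids):
        idx = pd.MultiIndex.from_arrays(
            [pids, list(range(len(values)))], names=["participant_id", "period_index"]
        )
        return pd.Series(values, index=idx, name="label")

    def test_predicts_training_majority(self):
        y = self._labels(
            [1, 1, 0, 0, 0, 0, 0, 0],
            ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
        )
        plan = FoldPlan(folds=[["P1"], ["P2"], ["P3"], ["P4"]], seed=0, group_size=1)
        res = majority_baseline(y, plan)
        p = res.prediction_series()
        # every training split has a clear 0 majority
        assert (p == 0).all()

    def test_tie_predicts_positive(self):
        y = self._labels([1, 0, 1, 0], ["P1", "P1", "P2", "P2"])
        plan = FoldPlan(folds=[["P1"], ["P2"]], seed=0, group_size=1)
        res = majority_baseline(y, plan)
        assert (res.prediction_series() == 1).all()

    def test_expected_accuracy_near_max_prevalence(self):
        rng = np.random.default_rng(0)
        n_pids, periods, p = 50, 8, 0.7
        pids = np.repeat([f"P{i:03d}" for i in range(n_pids)], periods)
        vals = rng.random(n_pids * periods) < p
        y = self._labels(vals.astype(int), list(pids))
        lab_df = y.reset_index()
        lab_df.columns = ["participant_id", "period_index", "label"]
        from mspheno.models import make_folds

        plan = make_folds(sorted(set(pids)), lab_df, group_size=5, seed=1)
        res = majority_baseline(y, plan)
        emp = float(np.mean(vals))
        assert res.metrics.accuracy == pytest.approx(max(emp, 1 - emp), abs=0.02)
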