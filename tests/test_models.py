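"""Fold construction, feature selection, and the per-sensor SVM CV."""

import numpy as np
import pandas as pd
import pytest

from mspheno.matrix import MissingPolicy, PeriodFeatureMatrix
from mspheno.models import fit_one_model, make_folds, select_features, FoldPlan


def _labels_for(pids, prevalences, periods=4):
    rows = []
    rng = np.random.default_rng(0)
    for pid, prev in zip(pids, prevalences):
        for k in range(1, periods + 1):
            rows.append((pid, "depression", k, int(rng.random() < prev)))
    return pd.DataFrame(rows, columns=["participant_id", "outcome", "period_index", "label"])


class TestMakeFolds:
    def test_104_participants_give_21_folds(self):
        pids = [f"P{i:03d}" for i in range(104)]
        plan = make_folds(pids, _labels_for(pids, [0.5] * 104), seed=1)
        sizes = sorted(len(f) for f in plan.folds)
        assert len(plan.folds) == 21
        assert sizes == [4] + [5] * 20

    def test_ten_participants_give_two_folds_of_five(self):
        pids = [f"P{i}" for i in range(10)]
        plan = make_folds(pids, _labels_for(pids, [0.5] * 10), seed=2)
        assert [len(f) for f in plan.folds] == [5, 5]

    def test_folds_partition_participants(self):
        pids = [f"P{i:03d}" for i in range(23)]
        plan = make_folds(pids, _labels_for(pids, [0.4] * 23), seed=3)
        flat = [p for f in plan.folds for p in f]
        assert sorted(flat) == sorted(pids)

    def test_stratification_balances_prevalence(self):
        rng = np.random.default_rng(4)
        pids = [f"P{i:03d}" for i in range(40)]
        prevs = rng.uniform(0.3, 0.7, size=40)
        labels = _labels_for(pids, prevs, periods=6)
        plan = make_folds(pids, labels, seed=4)
        overall = labels["label"].mean()
        per_p = labels.groupby("participant_id")["label"].mean()
        for fold in plan.folds:
            fold_prev = per_p.loc[list(fold)].mean()
            assert abs(fold_prev - overall) < 0.20

    def test_deterministic_given_seed(self):
        pids = [f"P{i}" for i in range(15)]
        labels = _labels_for(pids, [0.5] * 15)
        assert make_folds(pids, labels, seed=9).folds == make_folds(pids, labels, seed=9).folds

    def test_invalid_group_size(self):
        pids = [f"P{i}" for i in range(10)]
        with pytest.raises(ValueError):
            make_folds(pids, _labels_for(pids, [0.5] * 10), group_size=0)

    def test_overlapping_folds_rejected(self):
        with pytest.raises(ValueError):
            FoldPlan(folds=[["P1", "P2"], ["P2", "P3"]], seed=0)


class TestSelectFeatures:
    def test_duplicated_column_pruned_to_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        y = (a > 0).astype(int)
        feats = select_features(X, y)
        assert ("a" in feats) and ("b" not in feats)

    def test_constant_column_removed(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"const": np.zeros(40), "x": rng.normal(size=40)})
        y = rng.integers(0, 2, size=40)
        assert "const" not in select_features(X, y)

    def test_separating_column_ranked_first(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 25)
        X = pd.DataFrame(
            {f"noise{i}": rng.normal(size=50) for i in range(10)}
            | {"signal": y + 0.01 * rng.normal(size=50)}
        )
        feats = select_features(X, y, k_max=1)
        assert feats == ["signal"]

    def test_k_max_respected(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 50)), columns=[f"c{i:02d}" for i in range(50)])
        y = rng.integers(0, 2, size=60)
        assert len(select_features(X, y, k_max=10)) <= 10


def _toy_matrix(n_pids=8, periods=5, separable=True, seed=0, flip_last=False):
    """Small separable (or random) matrix shaped like a sensor matrix."""
    rng = np.random.default_rng(seed)
    rows, feats, labels = [], [], []
    for i in range(n_pids):
        for k in range(1, periods + 1):
            y = (i + k) % 2
            x = rng.normal(loc=3.0 * y if separable else 0.0, scale=0.5, size=4)
            rows.append((f"P{i+1:03d}", k))
            feats.append(x)
            labels.append(y)
    idx = pd.MultiIndex.from_tuples(rows, names=["participant_id", "period_index"])
    cols = [f"steps|all_day|all_days|f{j}|action" for j in range(4)]
    X = pd.DataFrame(np.array(feats), index=idx, columns=cols)
    y = pd.Series(labels, index=idx, name="label")
    nvd = pd.DataFrame(
        {f"n_valid_days|steps|{e}|{g}": 14 for e in ("all_day",) for g in ("all_days",)},
        index=idx,
    )
    if flip_last:
        y.iloc[-periods:] = 1 - y.iloc[-periods:]
    return PeriodFeatureMatrix(
        outcome="depression", variant="action_only", ema_mode="none",
        sensor_set=("steps",), period_weeks=2, X=X, y=y, nvd=nvd,
    )


def _plan(matrix, seed=0):
    pids = sorted(set(matrix.participants))
    lab = matrix.y.reset_index().rename(columns={0: "label"})
    lab.columns = ["participant_id", "period_index", "label"]
    return make_folds(pids, lab, group_size=4, seed=seed)


class TestFitOneModel:
    def test_separable_toy_reaches_perfect_f1(self):
        m = _toy_matrix(separable=True)
        res = fit_one_model(m, _plan(m), model_id="steps", C_grid=(1.0, 10.0), inner_splits=2)
        preds = (res.oof["probability"] >= 0.5).astype(int)
        assert (preds == res.oof["label"]).all()
        assert res.cv_f1 == 1.0

    def test_probabilities_bounded_and_out_of_fold(self):
        m = _toy_matrix(separable=False, seed=3)
        plan = _plan(m)
        res = fit_one_model(m, plan, model_id="steps", C_grid=(1.0,), inner_splits=2)
        assert res.oof["probability"].between(0, 1).all()
        # each sample's fold must be the fold holding out its participant
        fold_of = {p: i for i, fold in enumerate(plan.folds) for p in fold}
        assert (res.oof["participant_id"].map(fold_of) == res.oof["fold"]).all()

    def test_test_fold_labels_never_leak_into_training(self):
        # flipping the labels of one fold's test rows must not change that
        # fold's predictions (features unchanged)
        m = _toy_matrix(separable=False, seed=5)
        plan = _plan(m)
        res_a = fit_one_model(m, plan, model_id="steps", C_grid=(1.0,), inner_splits=2)
        target = plan.folds[0]
        y2 = m.y.copy()
        mask = np.isin(m.participants, target)
        y2.loc[mask] = 1 - y2.loc[mask]
        m2 = PeriodFeatureMatrix(
            outcome=m.outcome, variant=m.variant, ema_mode=m.ema_mode,
            sensor_set=m.sensor_set, period_weeks=m.period_weeks,
            X=m.X, y=y2, nvd=m.nvd,
        )
        res_b = fit_one_model(m2, plan, model_id="steps", C_grid=(1.0,), inner_splits=2)
        a = res_a.oof[res_a.oof["fold"] == 0]["probability"].to_numpy()
        b = res_b.oof[res_b.oof["fold"] == 0]["probability"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_single_class_training_split_predicts_constant(self):
        m = _toy_matrix(separable=True, seed=6)
        y1 = pd.Series(1, index=m.y.index, name="label")
        m1 = PeriodFeatureMatrix(
            outcome=m.outcome, variant=m.variant, ema_mode=m.ema_mode,
            sensor_set=m.sensor_set, period_weeks=m.period_weeks,
            X=m.X, y=y1, nvd=m.nvd,
        )
        res = fit_one_model(m1, _plan(m1), model_id="steps", C_grid=(1.0,))
        assert (res.oof["probability"] == 1.0).all()

    def test_permuted_labels_score_near_majority_rate(self):
        # permutation null: with labels shuffled, out-of-fold accuracy stays
        # inside a generous binomial band around the majority rate
        rng = np.random.default_rng(11)
        accs = []
        for rep in range(5):
            m = _toy_matrix(separable=False, seed=100 + rep)
            perm = rng.permutation(len(m.y))
            y = pd.Series(m.y.to_numpy()[perm], index=m.y.index, name="label")
            m2 = PeriodFeatureMatrix(
                outcome=m.outcome, variant=m.variant, ema_mode=m.ema_mode,
                sensor_set=m.sensor_set, period_weeks=m.period_weeks,
                X=m.X, y=y, nvd=m.nvd,
            )
            res = fit_one_model(m2, _plan(m2, seed=rep), C_grid=(1.0,), inner_splits=2)
            preds = (res.oof["probability"] >= 0.5).astype(int)
            accs.append((preds == res.oof["label"]).mean())
        n = 40
        majority = 0.5
        band = 3 * np.sqrt(majority * (1 - majority) / n)
        assert abs(np.mean(accs) - majority) < band
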