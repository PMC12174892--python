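"""Late-fusion ensemble over per-sensor / EMA model probabilities.

The positive-class out-of-fold probabilities of the member models are
stacked into a meta-feature matrix (one column per member, rows restricted
to the intersection of the members' sample sets) and combined with
AdaBoost over depth-1 decision trees, cross-validated on the same
leave-5-participants-out fold plan as the base models so no member ever
saw its own test participants. A combination ablation enumerates every
subset of size >= 2 of the model universe — 57 combinations for the 6
sensors, 120 when an EMA model joins the universe — and the best
combination per configuration is selected by out-of-fold F1 with a
parsimony tie-break.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import GroupKFold
from sklearn.tree import DecisionTreeClassifier

from .compare import MetricSet, evaluate, f1_score_binary
from .models import BaseModelResult, FoldPlan

log = logging.getLogger(__name__)

DEFAULT_N_ESTIMATORS_GRID: tuple[int, ...] = (10, 50, 100, 200)


@dataclass(frozen=True)
class Combination:
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))

    def __str__(self) -> str:
        return "+".join(self.members)

    def __len__(self) -> int:
        return len(self.members)


def enumerate_combinations(model_ids: list[str], min_size: int = 2) -> list[Combination]:
    """All subsets of the model universe with >= ``min_size`` members, in
    deterministic order (by size, then lexicographic). Six models yield 57
    combinations of size >= 2; seven yield 120 (2^n - n - 1)."""
    ids = sorted(model_ids)
    if len(ids) < min_size:
        raise ValueError(f"need at least {min_size} model ids")
    out = []
    for size in range(min_size, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            out.append(Combination(combo))
    return out


def stack_probabilities(
    combination: Combination, base_results: dict[str, BaseModelResult]
) -> pd.DataFrame:
    """Meta-feature matrix for one combination: one positive-probability
    column per member in deterministic member order, rows restricted to
    the intersection of the members' (participant, period) samples."""
    series = []
    for m in combination.members:
        s = base_results[m].probability_series()
        series.append(s.rename(m))
    meta = pd.concat(series, axis=1, join="inner")
    if meta.empty:
        raise ValueError(f"empty sample intersection for combination {combination}")
    return meta.sort_index()


@dataclass
class EnsembleResult:
    combination: Combination
    oof: pd.DataFrame  # participant_id, period_index, fold, prediction, label
    chosen_n_estimators: dict[int, int] = field(default_factory=dict)
    metrics: MetricSet | None = None

    def prediction_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_arrays(
            [self.oof["participant_id"], self.oof["period_index"]],
            names=["participant_id", "period_index"],
        )
        return pd.Series(self.oof["prediction"].to_numpy(), index=idx)


def _adaboost(n_estimators: int, seed: int) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1),
        n_estimators=n_estimators,
        random_state=seed,
    )


def _inner_f1_ada(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_estimators: int,
    inner_splits: int, seed: int,
) -> float:
    n_groups = len(np.unique(groups))
    n_splits = min(inner_splits, n_groups)
    if n_splits < 2:
        return 0.0
    preds = np.empty_like(y)
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            preds[te] = y[tr][0]
            continue
        clf = _adaboost(n_estimators, seed)
        clf.fit(X[tr], y[tr])
        preds[te] = clf.predict(X[te])
    return f1_score_binary(y, preds)


def fit_combiner(
    meta: pd.DataFrame,
    labels: pd.Series,
    fold_plan: FoldPlan,
    combination: Combination | None = None,
    n_estimators_grid: tuple[int, ...] = DEFAULT_N_ESTIMATORS_GRID,
    inner_splits: int = 3,
    seed: int = 0,
) -> EnsembleResult:
    """Cross-validated AdaBoost (depth-1 tree base) over stacked member
    probabilities.

    ``meta`` rows are (participant, period) indexed; ``labels`` must align.
    Per fold, n_estimators is chosen from the grid by inner group-wise F1
    (ties to the smallest); out-of-fold hard predictions are collected and
    summarized."""
    combination = combination or Combination(tuple(meta.columns))
    y = labels.reindex(meta.index).to_numpy(dtype=int)
    pids = meta.index.get_level_values("participant_id").to_numpy()
    X = meta.to_numpy(dtype=float)
    rows = []
    chosen: dict[int, int] = {}
    for fold_i, test_pids in enumerate(fold_plan.folds):
        test_mask = np.isin(pids, list(test_pids))
        train_mask = ~test_mask
        if not test_mask.any():
            continue
        ytr = y[train_mask]
        if len(np.unique(ytr)) < 2:
            log.info("combiner %s fold %d: single-class training split", combination, fold_i)
            pred = np.full(int(test_mask.sum()), int(ytr[0]) if ytr.size else 0)
            chosen[fold_i] = 0
        else:
            best_n = n_estimators_grid[0]
            if len(n_estimators_grid) > 1:  # nothing to tune otherwise
                best_f1 = -1.0
                for n_est in n_estimators_grid:
                    f1 = _inner_f1_ada(
                        X[train_mask], ytr, pids[train_mask], n_est, inner_splits, seed
                    )
                    if f1 > best_f1 + 1e-12:
                        best_n, best_f1 = n_est, f1
            clf = _adaboost(best_n, seed)
            clf.fit(X[train_mask], ytr)
            pred = clf.predict(X[test_mask])
            chosen[fold_i] = best_n
        for (pid, period), p, lab in zip(meta.index[test_mask], pred, y[test_mask]):
            rows.append((pid, period, fold_i, int(p), int(lab)))
    oof = pd.DataFrame(
        rows, columns=["participant_id", "period_index", "fold", "prediction", "label"]
    ).sort_values(["participant_id", "period_index"], ignore_index=True)
    metrics = evaluate(oof["prediction"].to_numpy(), oof["label"].to_numpy())
    return EnsembleResult(
        combination=combination, oof=oof, chosen_n_estimators=chosen, metrics=metrics
    )


def majority_baseline(labels: pd.Series, fold_plan: FoldPlan) -> EnsembleResult:
    """Per fold, predict the training split's majority label for every test
    row (exact ties predict positive)."""
    pids = labels.index.get_level_values("participant_id").to_numpy()
    y = labels.to_numpy(dtype=int)
    rows = []
    for fold_i, test_pids in enumerate(fold_plan.folds):
        test_mask = np.isin(pids, list(test_pids))
        if not test_mask.any():
            continue
        ytr = y[~test_mask]
        n_pos = int(ytr.sum())
        majority = 1 if n_pos * 2 >= ytr.size else 0
        for (pid, period), lab in zip(labels.index[test_mask], y[test_mask]):
            rows.append((pid, period, fold_i, majority, int(lab)))
    oof = pd.DataFrame(
        rows, columns=["participant_id", "period_index", "fold", "prediction", "label"]
    ).sort_values(["participant_id", "period_index"], ignore_index=True)
    metrics = evaluate(oof["prediction"].to_numpy(), oof["label"].to_numpy())
    return EnsembleResult(Combination(("majority",)), oof, {}, metrics)


def run_ablation(
    base_results: dict[str, BaseModelResult],
    labels: pd.Series,
    fold_plan: FoldPlan,
    min_size: int = 2,
    n_estimators_grid: tuple[int, ...] = DEFAULT_N_ESTIMATORS_GRID,
    inner_splits: int = 3,
    seed: int = 0,
) -> dict[Combination, EnsembleResult]:
    """Exhaustive combination ablation over the given model universe."""
    results: dict[Combination, EnsembleResult] = {}
    for combo in enumerate_combinations(sorted(base_results), min_size=min_size):
        meta = stack_probabilities(combo, base_results)
        results[combo] = fit_combiner(
            meta,
            labels,
            fold_plan,
            combination=combo,
            n_estimators_grid=n_estimators_grid,
            inner_splits=inner_splits,
            seed=seed,
        )
    return results


def select_best(
    results: dict[Combination, EnsembleResult], criterion: str = "f1"
) -> Combination:
    """Best combination by the criterion (default out-of-fold F1); ties
    break toward fewer members, then lexicographically."""
    if not results:
        raise ValueError("no ablation results to select from")
    def sort_key(item: tuple[Combination, EnsembleResult]):
        combo, res = item
        value = getattr(res.metrics, criterion)
        return (-value, len(combo), combo.members)
    return min(results.items(), key=sort_key)[0]


def ablation_table(
    results: dict[Combination, EnsembleResult],
    outcome: str,
    variant: str,
    ema_mode: str,
) -> pd.DataFrame:
    rows = []
    for combo, res in results.items():
        m = res.metrics
        rows.append(
            (
                outcome, variant, ema_mode, str(combo), len(combo),
                m.accuracy, m.f1, m.precision, m.recall, m.n_samples,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome", "variant", "ema_mode", "combination", "size",
            "accuracy", "f1", "precision", "recall", "n_samples",
        ],
    )
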