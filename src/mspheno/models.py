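"""Per-sensor and EMA-only classifiers with leave-5-participants-out CV.

Each 1-sensor (or EMA-only) model is an RBF-kernel SVM with balanced class
weights and Platt-style probability outputs. Validation is subject-wise:
participants are partitioned into folds of 5 (stratified on participant-
level positive prevalence), and every sample's probability comes from a
model whose training split excluded that sample's participant. Inside each
training split the pipeline standardizes columns, applies the fold-aware
missing-data transform, prunes redundant features, and picks the SVM
regularization constant C by inner cross-validated F1 (ties go to the
smallest C).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .compare import f1_score_binary
from .matrix import (
    MissingPolicy,
    PeriodFeatureMatrix,
    fit_missing_transform,
    mask_low_coverage,
)

log = logging.getLogger(__name__)

DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)


@dataclass
class FoldPlan:
    """Partition of participants into test groups of (up to) ``group_size``."""

    folds: list[list[str]]
    seed: int
    group_size: int = 5

    def __post_init__(self) -> None:
        flat = [p for fold in self.folds for p in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must be disjoint")

    @property
    def participants(self) -> set[str]:
        return {p for fold in self.folds for p in fold}


def make_folds(
    participants: list[str],
    labels: pd.DataFrame,
    group_size: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Stratified leave-``group_size``-participants-out fold plan.

    Participants are shuffled with ``seed``, sorted by descending
    positive-label prevalence (the shuffle breaks ties), and dealt to the
    folds in serpentine order so each fold receives a balanced spread of
    high- and low-prevalence participants. The last fold may be smaller
    than ``group_size``."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    participants = list(participants)
    n_folds = -(-len(participants) // group_size)
    if n_folds < 2:
        raise ValueError("need at least 2 folds of participants")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(participants))
    prev = labels.groupby("participant_id")["label"].mean()
    order.sort(key=lambda p: -float(prev.get(p, 0.0)))  # stable: shuffle breaks ties

    sizes = [group_size] * (n_folds - 1) + [len(participants) - group_size * (n_folds - 1)]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    direction = 1
    lane = 0
    for p in order:
        tried = 0
        while len(folds[lane]) >= sizes[lane] and tried <= n_folds:
            lane += direction
            if lane in (-1, n_folds):
                direction *= -1
                lane += direction
            tried += 1
        folds[lane].append(p)
        lane += direction
        if lane in (-1, n_folds):
            direction *= -1
            lane += direction
    return FoldPlan(folds=folds, seed=seed, group_size=group_size)


# --------------------------------------------------------------------------
# feature selection
# --------------------------------------------------------------------------
def select_features(
    train_X: pd.DataFrame, train_y: np.ndarray, k_max: int = 30
) -> list[str]:
    """Redundancy-pruning filter selection on training rows only.

    Drops near-constant columns, keeps the first (in manifest order) of any
    pair with |Pearson r| >= 0.9, then ranks the survivors by point-biserial
    correlation magnitude with the label and keeps the top ``k_max``. If
    nothing survives, falls back to the single best-correlated column."""
    X = train_X.to_numpy(dtype=float)
    cols = list(train_X.columns)
    var = X.var(axis=0)
    alive = var > 1e-12
    if not alive.any():
        return [cols[0]] if cols else []
    idx = np.flatnonzero(alive)
    Xa = X[:, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Xa, rowvar=False)
        if corr.ndim == 0:
            corr = np.array([[1.0]])
        keep_mask = np.ones(idx.size, dtype=bool)
        for a in range(idx.size):
            if not keep_mask[a]:
                continue
            dup = np.abs(corr[a]) >= 0.9
            dup[: a + 1] = False
            keep_mask[dup] = False
        kept = idx[keep_mask]
        y = np.asarray(train_y, dtype=float)
        yc = y - y.mean()
        Xc = X[:, kept] - X[:, kept].mean(axis=0)
        r = np.abs(Xc.T @ yc) / (
            np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc) + 1e-30
        )
    order = np.argsort(-r, kind="stable")[:k_max]
    chosen = sorted(kept[order])  # manifest order
    return [cols[i] for i in chosen]


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------
@dataclass
class BaseModelResult:
    """Out-of-fold probabilities and per-fold fit details for one model."""

    model_id: str
    oof: pd.DataFrame  # participant_id, period_index, fold, probability, label
    chosen_C: dict[int, float] = field(default_factory=dict)
    selected_features: dict[int, list[str]] = field(default_factory=dict)
    cv_f1: float = float("nan")

    def probability_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_arrays(
            [self.oof["participant_id"], self.oof["period_index"]],
            names=["participant_id", "period_index"],
        )
        return pd.Series(self.oof["probability"].to_numpy(), index=idx)


def _inner_f1(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, C: float, inner_splits: int, seed: int
) -> float:
    """Mean F1 of an SVC(C) over an inner group-wise split of the training
    data (decision-function predictions; no probability calibration)."""
    n_groups = len(np.unique(groups))
    n_splits = min(inner_splits, n_groups)
    if n_splits < 2:
        return 0.0
    preds = np.empty_like(y)
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        if len(np.unique(y[tr])) < 2:
            preds[te] = y[tr][0]
            continue
        clf = SVC(C=C, kernel="rbf", gamma="scale", class_weight="balanced")
        clf.fit(X[tr], y[tr])
        preds[te] = clf.predict(X[te])
    return f1_score_binary(y, preds)


def fit_one_model(
    matrix: PeriodFeatureMatrix,
    fold_plan: FoldPlan,
    model_id: str | None = None,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    policy: MissingPolicy | None = None,
    k_max: int = 30,
    inner_splits: int = 3,
    seed: int = 0,
) -> BaseModelResult:
    """Train one sensor/EMA model with leave-5-participants-out CV.

    Per fold: fit the missing-data transform, standardization, feature
    selection and the C choice on the training split only, then record
    Platt-calibrated positive-class probabilities for the held-out rows. A
    single-class training split predicts its constant class with
    probability 1."""
    policy = policy or MissingPolicy()
    masked = mask_low_coverage(matrix, policy)
    model_id = model_id or (
        matrix.sensor_set[0] if matrix.sensor_set else f"ema_{matrix.ema_mode}"
    )
    # retain-and-intersect rule: this model simply lacks rows for which its
    # sensor recorded nothing at all; fusion later intersects member rows
    has_any = ~masked.X.isna().all(axis=1)
    if not has_any.all():
        masked = replace(
            masked,
            X=masked.X.loc[has_any],
            y=masked.y.loc[has_any],
            nvd=masked.nvd.loc[has_any],
            nvd_context=(
                masked.nvd_context.loc[has_any]
                if masked.nvd_context is not None
                else None
            ),
        )
    pids = masked.participants
    y_all = masked.y.to_numpy(dtype=int)
    rows = []
    chosen_C: dict[int, float] = {}
    selected: dict[int, list[str]] = {}
    for fold_i, test_pids in enumerate(fold_plan.folds):
        test_mask = np.isin(pids, list(test_pids))
        train_mask = ~test_mask
        if not test_mask.any():
            continue
        Xtr_raw = masked.X.loc[train_mask]
        ytr = y_all[train_mask]
        transform = fit_missing_transform(Xtr_raw, policy)
        Xtr = transform.apply(Xtr_raw)
        Xte = transform.apply(masked.X.loc[test_mask])
        test_index = masked.X.index[test_mask]

        if len(np.unique(ytr)) < 2 or Xtr.shape[1] == 0:
            const = int(ytr[0]) if len(ytr) else 0
            log.info("%s fold %d: single-class training split", model_id, fold_i)
            prob = np.full(int(test_mask.sum()), float(const))
            chosen_C[fold_i] = float("nan")
            selected[fold_i] = []
        else:
            scaler = StandardScaler().fit(Xtr)
            Xtr_s = pd.DataFrame(scaler.transform(Xtr), columns=Xtr.columns)
            Xte_s = pd.DataFrame(scaler.transform(Xte), columns=Xte.columns)
            feats = select_features(Xtr_s, ytr, k_max=k_max)
            Xtr_f = Xtr_s[feats].to_numpy()
            Xte_f = Xte_s[feats].to_numpy()
            groups_tr = pids[train_mask]
            best_C = C_grid[0]
            if len(C_grid) > 1:
                best_f1 = -1.0
                for C in C_grid:  # ties -> smallest C
                    f1 = _inner_f1(Xtr_f, ytr, groups_tr, C, inner_splits, seed)
                    if f1 > best_f1 + 1e-12:
                        best_C, best_f1 = C, f1
            clf = SVC(
                C=best_C,
                kernel="rbf",
                gamma="scale",
                class_weight="balanced",
                probability=True,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(Xtr_f, ytr)
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            prob = clf.predict_proba(Xte_f)[:, pos_col]
            chosen_C[fold_i] = best_C
            selected[fold_i] = feats
        for (pid, period), p, lab in zip(test_index, prob, y_all[test_mask]):
            rows.append((pid, period, fold_i, float(p), int(lab)))

    oof = pd.DataFrame(
        rows, columns=["participant_id", "period_index", "fold", "probability", "label"]
    ).sort_values(["participant_id", "period_index"], ignore_index=True)
    preds = (oof["probability"].to_numpy() >= 0.5).astype(int)
    cv_f1 = f1_score_binary(oof["label"].to_numpy(), preds)
    return BaseModelResult(
        model_id=model_id,
        oof=oof,
        chosen_C=chosen_C,
        selected_features=selected,
        cv_f1=cv_f1,
    )
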