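"""Assemble action / action+context feature matrices aligned to labels.

To predict the outcome at the end of period *i* (of length P = 2 or 4
weeks), the *action* matrix uses features computed over period *i* itself
(the window immediately preceding the prediction point), and the *action
and context* matrix additionally concatenates the same features computed
over period *i-1*. Context columns therefore equal the corresponding
action column shifted by one period within participant, and rows whose
participant lacks period *i-1* are dropped from the action+context
variant.

The missing-data policy has three steps:

1. a sensor's features in a slice are set missing for a period when fewer
   than ``min_valid_day_fraction`` of that slice's days had any data;
2. columns missing in more than ``max_col_missing_fraction`` of *training*
   rows are dropped;
3. remaining missing cells are imputed with the column median computed on
   training rows only (fold-aware: imputation statistics are fit per CV
   training split and applied to its test split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import DAY_GROUPS, EMA_QUESTIONS, EPOCHS, SENSORS
from .features import FEATURES_BY_SENSOR, feature_column, period_columns

log = logging.getLogger(__name__)

EMA_MODES = ("none", "presurvey", "average")
VARIANTS = ("action_only", "action_context")


@dataclass
class MissingPolicy:
    min_valid_day_fraction: float = 0.5
    max_col_missing_fraction: float = 0.4

    def __post_init__(self) -> None:
        for name in ("min_valid_day_fraction", "max_col_missing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class PeriodFeatureMatrix:
    """Feature matrix for one (outcome, variant, ema_mode) configuration.

    ``X`` rows are (participant_id, period_index) samples; columns are
    ``sensor|epoch|day_group|feature|{action,context}`` or
    ``ema_{mode}|{question}|{action,context}``. ``nvd`` / ``nvd_context``
    carry the per-slice valid-day counters used by the coverage rule.
    """

    outcome: str
    variant: str
    ema_mode: str
    sensor_set: tuple[str, ...]
    period_weeks: int
    X: pd.DataFrame
    y: pd.Series
    nvd: pd.DataFrame
    nvd_context: pd.DataFrame | None = None

    @property
    def participants(self) -> np.ndarray:
        return self.X.index.get_level_values("participant_id").to_numpy()

    def column_manifest(self) -> pd.DataFrame:
        rows = []
        for col in self.X.columns:
            parts = col.split("|")
            tag = parts[-1]
            if parts[0].startswith("ema_"):
                rows.append((col, "ema", parts[0][4:], "", parts[1], tag))
            else:
                sensor, epoch, dg, feat = parts[:4]
                rows.append((col, sensor, epoch, dg, feat, tag))
        return pd.DataFrame(
            rows, columns=["column", "sensor", "epoch", "day_group", "feature", "tag"]
        )


def _ema_columns(ema_mode: str) -> list[str]:
    return [f"ema_{ema_mode}|{q}" for q in EMA_QUESTIONS]


def build_matrix(
    period_features: pd.DataFrame,
    ema_features: pd.DataFrame | None,
    labels: pd.DataFrame,
    variant: str,
    sensor_set: tuple[str, ...],
    ema_mode: str,
    period_weeks: int,
) -> PeriodFeatureMatrix:
    """Align per-period features and EMA features to labels for one outcome.

    ``period_features`` is the wide per-(participant, period) sensor table
    on this outcome's period grid (including n_valid_days counters);
    ``ema_features`` carries columns ``ema_average|q`` / ``ema_presurvey|q``
    on the same grid. Column order is deterministic: sensors in canonical
    order, then EMA, action block before context block.
    """
    if ema_mode not in EMA_MODES:
        raise ValueError(f"ema_mode must be one of {EMA_MODES}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    sensor_set = tuple(s for s in SENSORS if s in sensor_set)
    if not sensor_set and ema_mode == "none":
        raise ValueError("empty sensor set with ema_mode='none'")

    outcome = labels["outcome"].iloc[0] if len(labels) else ""
    base_cols = period_columns(sensor_set)
    nvd_cols = [
        f"n_valid_days|{s}|{e}|{g}"
        for s in sensor_set
        for e in EPOCHS
        for g in DAY_GROUPS
    ]
    pf = period_features.set_index(["participant_id", "period_index"]).sort_index()
    base = pf.reindex(columns=base_cols)
    nvd_base = pf.reindex(columns=nvd_cols)
    if ema_mode != "none":
        ef = ema_features.set_index(["participant_id", "period_index"]).sort_index()
        base = base.join(ef.reindex(columns=_ema_columns(ema_mode)), how="left")

    lab = labels.sort_values(["participant_id", "period_index"], kind="stable")
    rows = pd.MultiIndex.from_arrays(
        [lab["participant_id"], lab["period_index"]],
        names=["participant_id", "period_index"],
    )
    y = pd.Series(lab["label"].to_numpy(), index=rows, name="label")

    action = base.reindex(rows)
    have_action = rows.isin(base.index)
    nvd = nvd_base.reindex(rows)
    action.columns = [f"{c}|action" for c in action.columns]

    if variant == "action_only":
        keep = have_action
        X = action.loc[keep]
        return PeriodFeatureMatrix(
            outcome, variant, ema_mode, sensor_set, period_weeks,
            X, y.loc[keep], nvd.loc[keep],
        )

    prev_rows = pd.MultiIndex.from_arrays(
        [rows.get_level_values(0), rows.get_level_values(1) - 1],
        names=["participant_id", "period_index"],
    )
    have_context = prev_rows.isin(base.index)
    context = base.reindex(prev_rows)
    context.index = rows
    context.columns = [f"{c}|context" for c in context.columns]
    nvd_ctx = nvd_base.reindex(prev_rows)
    nvd_ctx.index = rows
    keep = have_action & have_context
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("%s/%s: dropped %d rows lacking a context period", outcome, variant, n_drop)
    X = pd.concat([action, context], axis=1).loc[keep]
    return PeriodFeatureMatrix(
        outcome, variant, ema_mode, sensor_set, period_weeks,
        X, y.loc[keep], nvd.loc[keep], nvd_ctx.loc[keep],
    )


# --------------------------------------------------------------------------
# missing-data policy
# --------------------------------------------------------------------------
def _group_days(period_weeks: int, day_group: str) -> int:
    return period_weeks * {"all_days": 7, "weekdays": 5, "weekends": 2}[day_group]


def mask_low_coverage(matrix: PeriodFeatureMatrix, policy: MissingPolicy) -> PeriodFeatureMatrix:
    """Step 1 of the policy: blank a sensor-slice's features for rows where
    the slice had data on fewer than the required fraction of its days.
    Row-local, hence fold-independent."""
    X = matrix.X.copy()
    for tag, nvd in (("action", matrix.nvd), ("context", matrix.nvd_context)):
        if nvd is None:
            continue
        for sensor in matrix.sensor_set:
            for epoch in EPOCHS:
                for dg in DAY_GROUPS:
                    need = policy.min_valid_day_fraction * _group_days(
                        matrix.period_weeks, dg
                    )
                    counter = f"n_valid_days|{sensor}|{epoch}|{dg}"
                    if counter not in nvd.columns:
                        continue
                    sparse = nvd[counter].fillna(0).to_numpy() < need
                    if not sparse.any():
                        continue
                    cols = [
                        f"{feature_column(sensor, epoch, dg, f)}|{tag}"
                        for f in FEATURES_BY_SENSOR[sensor]
                    ]
                    X.loc[sparse, cols] = np.nan
    return replace(matrix, X=X)


@dataclass
class MissingTransform:
    """Fold-aware column filter + median imputer, fit on training rows only."""

    kept_columns: list[str]
    medians: pd.Series
    dropped_columns: list[str] = field(default_factory=list)

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.reindex(columns=self.kept_columns)
        return out.fillna(self.medians)


def fit_missing_transform(X_train: pd.DataFrame, policy: MissingPolicy) -> MissingTransform:
    """Steps 2-3: drop columns too often missing in training rows, and learn
    training-row medians for imputing the rest."""
    frac_missing = X_train.isna().mean(axis=0)
    kept = [
        c
        for c in X_train.columns
        if frac_missing[c] <= policy.max_col_missing_fraction
        and not X_train[c].isna().all()
    ]
    medians = X_train[kept].median(axis=0)
    dropped = [c for c in X_train.columns if c not in kept]
    return MissingTransform(kept, medians, dropped)


def apply_missing_policy(
    matrix: PeriodFeatureMatrix,
    policy: MissingPolicy,
    train_mask: np.ndarray | None = None,
) -> tuple[PeriodFeatureMatrix, dict]:
    """Apply the full policy to a matrix.

    ``train_mask`` marks the rows whose statistics may be used for column
    dropping and imputation (defaults to all rows). Rows entirely missing
    after the policy are dropped and reported."""
    masked = mask_low_coverage(matrix, policy)
    if train_mask is None:
        train_mask = np.ones(len(masked.X), dtype=bool)
    transform = fit_missing_transform(masked.X.loc[train_mask], policy)
    all_missing = masked.X.reindex(columns=transform.kept_columns).isna().all(axis=1)
    X = transform.apply(masked.X.loc[~all_missing])
    y = masked.y.loc[~all_missing]
    nvd = masked.nvd.loc[~all_missing]
    nvd_ctx = masked.nvd_context.loc[~all_missing] if masked.nvd_context is not None else None
    n_dropped_rows = int(all_missing.sum())
    if n_dropped_rows:
        log.info("%s: dropped %d all-missing rows", matrix.outcome, n_dropped_rows)
    report = {
        "n_dropped_columns": len(transform.dropped_columns),
        "dropped_columns": transform.dropped_columns,
        "n_dropped_rows": n_dropped_rows,
        "n_rows": len(X),
        "n_columns": X.shape[1],
    }
    return replace(masked, X=X, y=y, nvd=nvd, nvd_context=nvd_ctx), report
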