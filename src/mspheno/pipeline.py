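"""End-to-end orchestration: cohort -> features -> labels -> matrices ->
base models -> fusion ablation -> model comparison.

For every outcome the pipeline runs the six-configuration sweep
({no, presurvey, average} EMA x {action-only, action+context}), trains the
six 1-sensor models (plus the EMA-only model where applicable) with
leave-5-participants-out CV, runs the exhaustive combination ablation
(57 sensor combinations, 120 with EMA), selects the best combination per
configuration by out-of-fold F1, and compares the six final models with
the paired hierarchical bootstrap and the parsimony rule.

A persisted :class:`RunConfig` fully reproduces a run: all randomness
derives from the seeds it carries, and rerunning writes bit-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import (
    ComparisonResult,
    MetricSet,
    ParsimonyScore,
    bootstrap_paired_diff,
    select_preferred,
)
from .constants import EMA_QUESTIONS, OUTCOMES, SENSORS
from .features import compute_daily_features, compute_ema_features, period_features_for_participant
from .fusion import (
    Combination,
    EnsembleResult,
    ablation_table,
    majority_baseline,
    run_ablation,
    select_best,
)
from .labels import build_labels, build_schedule
from .matrix import EMA_MODES, VARIANTS, MissingPolicy, build_matrix
from .models import DEFAULT_C_GRID, BaseModelResult, FoldPlan, fit_one_model, make_folds
from .synthetic import CohortConfig, GeneratedDataset, generate_cohort, write_dataset

log = logging.getLogger(__name__)

CONFIGURATIONS: tuple[tuple[str, str], ...] = tuple(
    (variant, ema_mode) for variant in VARIANTS for ema_mode in EMA_MODES
)


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    policy: MissingPolicy = field(default_factory=MissingPolicy)
    outcomes: tuple[str, ...] = OUTCOMES
    sensors: tuple[str, ...] = SENSORS
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_estimators_grid: tuple[int, ...] = (10, 50, 100, 200)
    inner_splits: int = 3
    k_max: int = 30
    group_size: int = 5
    fold_seed: int = 1
    model_seed: int = 2
    bootstrap_seed: int = 3
    n_bootstrap: int = 10_000
    hierarchical_bootstrap: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "policy" in d and isinstance(d["policy"], dict):
            d["policy"] = MissingPolicy(**d["policy"])
        for key in ("outcomes", "sensors", "C_grid", "n_estimators_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------
@dataclass
class FeatureTables:
    """Per-period sensor and EMA feature tables keyed by period length."""

    daily: dict[str, pd.DataFrame]  # pid -> (date, epoch, sensor, feature, value)
    period: dict[int, pd.DataFrame]  # period weeks -> wide table
    ema: dict[int, pd.DataFrame]


def build_feature_tables(dataset: GeneratedDataset, schedule: pd.DataFrame) -> FeatureTables:
    daily: dict[str, pd.DataFrame] = {}
    for pid in dataset.participant_ids:
        daily[pid] = compute_daily_features(dataset.streams[pid], pid)

    period_weeks_used = sorted(
        set(dataset.config.period_len_weeks_by_outcome[o] for o in OUTCOMES)
    )
    outcome_for_plen = {
        dataset.config.period_len_weeks_by_outcome[o]: o for o in OUTCOMES
    }
    period_tables: dict[int, pd.DataFrame] = {}
    ema_tables: dict[int, pd.DataFrame] = {}
    ema_by_pid = {pid: g for pid, g in dataset.ema.groupby("participant_id")}
    for plen in period_weeks_used:
        rep = outcome_for_plen[plen]
        grid = schedule.loc[schedule["outcome"] == rep]
        frames = []
        ema_rows = []
        for pid, periods in grid.groupby("participant_id"):
            pf = period_features_for_participant(
                daily[pid].drop(columns=["participant_id"], errors="ignore"),
                periods[["period_index", "period_start", "survey_date"]],
            )
            pf.insert(0, "participant_id", pid)
            frames.append(pf)
            ema_p = ema_by_pid.get(pid, dataset.ema.iloc[0:0])
            for rec in periods.itertuples(index=False):
                ef = compute_ema_features(
                    ema_p, rec.period_start, rec.survey_date, rec.period_index, pid
                )
                row = {"participant_id": pid, "period_index": rec.period_index}
                for q in EMA_QUESTIONS:
                    row[f"ema_average|{q}"] = ef.avg_ema[q]
                    row[f"ema_presurvey|{q}"] = ef.presurvey_ema[q]
                ema_rows.append(row)
        period_tables[plen] = pd.concat(frames, ignore_index=True)
        ema_tables[plen] = pd.DataFrame(ema_rows)
    return FeatureTables(daily=daily, period=period_tables, ema=ema_tables)


# --------------------------------------------------------------------------
# one outcome
# --------------------------------------------------------------------------
@dataclass
class FinalModel:
    outcome: str
    variant: str
    ema_mode: str
    best_combination: Combination
    result: EnsembleResult
    baseline: EnsembleResult
    parsimony: ParsimonyScore

    @property
    def model_id(self) -> str:
        return f"{self.variant}|{self.ema_mode}"


@dataclass
class OutcomeRun:
    outcome: str
    fold_plan: FoldPlan
    base_results: dict[tuple[str, str], BaseModelResult]  # (variant, model_id)
    finals: dict[tuple[str, str], FinalModel]  # (variant, ema_mode)
    ablation: pd.DataFrame
    comparisons: list[ComparisonResult]
    preferred: str

    def summary_table(self) -> pd.DataFrame:
        """Table-2-shaped summary: one row per final-model configuration."""
        rows = []
        for (variant, ema_mode), fm in sorted(self.finals.items()):
            m = fm.result.metrics
            rows.append(
                (
                    self.outcome, variant, ema_mode, str(fm.best_combination),
                    round(100 * m.accuracy, 1), round(m.f1, 2),
                    round(m.precision, 2), round(m.recall, 2), m.n_samples,
                    round(100 * fm.baseline.metrics.accuracy, 1),
                    fm.model_id == self.preferred,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "outcome", "variant", "ema_mode", "best_combination",
                "accuracy_pct", "f1", "precision", "recall", "n_samples",
                "baseline_accuracy_pct", "preferred",
            ],
        )


def run_outcome(
    outcome: str,
    tables: FeatureTables,
    labels_df: pd.DataFrame,
    config: RunConfig,
) -> OutcomeRun:
    """The full six-configuration sweep for one outcome."""
    plen = config.cohort.period_len_weeks_by_outcome[outcome]
    lab = labels_df.loc[labels_df["outcome"] == outcome]
    if lab.empty:
        raise ValueError(f"no labels for outcome {outcome}")
    participants = sorted(lab["participant_id"].unique())
    fold_plan = make_folds(participants, lab, config.group_size, config.fold_seed)

    base_results: dict[tuple[str, str], BaseModelResult] = {}
    for variant in VARIANTS:
        for sensor in config.sensors:
            mtx = build_matrix(
                tables.period[plen], None, lab, variant, (sensor,), "none", plen
            )
            base_results[(variant, sensor)] = fit_one_model(
                mtx, fold_plan, model_id=sensor,
                C_grid=config.C_grid, policy=config.policy,
                k_max=config.k_max, inner_splits=config.inner_splits,
                seed=config.model_seed,
            )
        for ema_mode in ("presurvey", "average"):
            mtx = build_matrix(
                tables.period[plen], tables.ema[plen], lab, variant, (), ema_mode, plen
            )
            model_id = f"ema_{ema_mode}"
            base_results[(variant, model_id)] = fit_one_model(
                mtx, fold_plan, model_id=model_id,
                C_grid=config.C_grid, policy=config.policy,
                k_max=config.k_max, inner_splits=config.inner_splits,
                seed=config.model_seed,
            )

    label_series = pd.Series(
        lab["label"].to_numpy(dtype=int),
        index=pd.MultiIndex.from_arrays(
            [lab["participant_id"], lab["period_index"]],
            names=["participant_id", "period_index"],
        ),
    )

    finals: dict[tuple[str, str], FinalModel] = {}
    ablation_frames = []
    for variant, ema_mode in CONFIGURATIONS:
        universe = {s: base_results[(variant, s)] for s in config.sensors}
        if ema_mode != "none":
            mid = f"ema_{ema_mode}"
            universe[mid] = base_results[(variant, mid)]
        results = run_ablation(
            universe, label_series, fold_plan,
            n_estimators_grid=config.n_estimators_grid,
            inner_splits=config.inner_splits, seed=config.model_seed,
        )
        ablation_frames.append(ablation_table(results, outcome, variant, ema_mode))
        best = select_best(results, criterion="f1")
        best_res = results[best]
        base_rows = label_series.reindex(best_res.prediction_series().index)
        baseline = majority_baseline(base_rows, fold_plan)
        n_sensors = sum(1 for m in best.members if not m.startswith("ema_"))
        # burden is rated at configuration level: an EMA-mode configuration
        # requires EMA collection even if its best combination skipped the
        # EMA member
        parsimony = ParsimonyScore.from_config(ema_mode, variant, n_sensors)
        finals[(variant, ema_mode)] = FinalModel(
            outcome, variant, ema_mode, best, best_res, baseline, parsimony
        )

    # pairwise hierarchical bootstrap over the six final models
    comparisons: list[ComparisonResult] = []
    ids = {fm.model_id: fm for fm in finals.values()}
    ordered = sorted(ids)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            pa = ids[a].result.prediction_series()
            pb = ids[b].result.prediction_series()
            shared = pa.index.intersection(pb.index)
            comparisons.append(
                bootstrap_paired_diff(
                    pa.reindex(shared).to_numpy(),
                    pb.reindex(shared).to_numpy(),
                    label_series.reindex(shared).to_numpy(),
                    shared.get_level_values("participant_id").to_numpy(),
                    n_iter=config.n_bootstrap,
                    seed=config.bootstrap_seed,
                    model_a=a,
                    model_b=b,
                    hierarchical=config.hierarchical_bootstrap,
                )
            )
    parsimony = {fm.model_id: fm.parsimony for fm in finals.values()}
    metrics: dict[str, MetricSet] = {fm.model_id: fm.result.metrics for fm in finals.values()}
    preferred = select_preferred(comparisons, parsimony, metrics)
    return OutcomeRun(
        outcome=outcome,
        fold_plan=fold_plan,
        base_results=base_results,
        finals=finals,
        ablation=pd.concat(ablation_frames, ignore_index=True),
        comparisons=comparisons,
        preferred=preferred,
    )


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------
@dataclass
class RunResult:
    config: RunConfig
    dataset: GeneratedDataset
    schedule: pd.DataFrame
    labels: pd.DataFrame
    tables: FeatureTables
    outcome_runs: dict[str, OutcomeRun]

    def summary(self) -> pd.DataFrame:
        return pd.concat(
            [r.summary_table() for r in self.outcome_runs.values()], ignore_index=True
        )


def comparisons_table(run: OutcomeRun) -> pd.DataFrame:
    rows = []
    for c in run.comparisons:
        rows.append(
            (
                run.outcome, c.model_a, c.model_b,
                c.point_acc_diff, c.ci_acc_diff[0], c.ci_acc_diff[1], c.significant_acc,
                c.point_f1_diff, c.ci_f1_diff[0], c.ci_f1_diff[1], c.significant_f1,
                c.n_iterations, c.seed, run.preferred,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome", "model_a", "model_b",
            "acc_diff", "acc_ci_low", "acc_ci_high", "significant_acc",
            "f1_diff", "f1_ci_low", "f1_ci_high", "significant_f1",
            "n_iterations", "seed", "preferred_model",
        ],
    )


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the whole pipeline; optionally write all artifacts."""
    t0 = time.time()
    dataset = generate_cohort(config.cohort)
    log.info("generated cohort: %d participants, %d weeks (%.1fs)",
             config.cohort.n_participants, config.cohort.n_weeks, time.time() - t0)
    enrollments = {p.participant_id: p.enrollment_date for p in dataset.participants}
    schedule = build_schedule(
        enrollments, config.cohort.n_weeks, config.cohort.period_len_weeks_by_outcome
    )
    labels_df = build_labels(dataset.questionnaires, schedule)
    t1 = time.time()
    tables = build_feature_tables(dataset, schedule)
    log.info("feature extraction done (%.1fs)", time.time() - t1)
    outcome_runs = {}
    for outcome in config.outcomes:
        t2 = time.time()
        outcome_runs[outcome] = run_outcome(outcome, tables, labels_df, config)
        log.info("outcome %s done (%.1fs)", outcome, time.time() - t2)
    result = RunResult(config, dataset, schedule, labels_df, tables, outcome_runs)
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------
def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: RunResult, out_dir: str | Path, raw_streams: bool = False) -> dict:
    """Write all documented CSV artifacts plus a machine-readable manifest.

    Returns the manifest (also written as ``run_manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if raw_streams:
        write_dataset(result.dataset, out / "raw")
    result.labels.to_csv(out / "labels.csv", index=False)
    sched = result.schedule.copy()
    sched.to_csv(out / "schedule.csv", index=False)
    for plen, table in result.tables.period.items():
        table.to_csv(out / f"period_features_{plen}w.csv", index=False)
    for plen, table in result.tables.ema.items():
        table.to_csv(out / f"ema_features_{plen}w.csv", index=False)
    for outcome, run in result.outcome_runs.items():
        odir = out / outcome
        odir.mkdir(exist_ok=True)
        run.ablation.to_csv(odir / "ablation.csv", index=False)
        run.summary_table().to_csv(odir / "final_models.csv", index=False)
        comparisons_table(run).to_csv(odir / "comparisons.csv", index=False)
        for (variant, model_id), res in sorted(run.base_results.items()):
            res.oof.to_csv(odir / f"oof_{variant}_{model_id}.csv", index=False)
    files = sorted(str(p.relative_to(out)) for p in out.rglob("*.csv"))
    manifest = {
        "config": result.config.to_dict(),
        "dataset_hash": result.dataset.content_hash(),
        "preferred_models": {
            o: r.preferred for o, r in result.outcome_runs.items()
        },
        "artifacts": {f: _sha256(out / f) for f in files},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
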