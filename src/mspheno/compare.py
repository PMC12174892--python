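"""Model comparison: metrics, hierarchical paired bootstrap, parsimony rule.

The six final models per outcome (EMA mode x feature variant) are compared
pairwise (15 pairs x 2 metrics = 30 comparisons) through a paired
hierarchical bootstrap: each iteration resamples participants with
replacement and, within each drawn participant, their prediction periods
with replacement; the same resampled index set is applied to both models
of the pair, and percentile 95% CIs of the accuracy and F1 differences are
formed over (by default) 10,000 iterations. A model is "statistically
better" when at least one metric's CI excludes zero in its favor and the
other metric's CI does not exclude zero against it. When neither model of
a pair is statistically better, the one requiring less data wins: no EMA
beats presurvey EMA beats average EMA, action-only beats action+context,
fewer sensors beat more.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
def f1_score_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 for the positive (symptom-present) class; 0 when undefined."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.count_nonzero((y_pred == 1) & (y_true == 1)))
    fp = int(np.count_nonzero((y_pred == 1) & (y_true == 0)))
    fn = int(np.count_nonzero((y_pred == 0) & (y_true == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class MetricSet:
    accuracy: float
    f1: float
    precision: float
    recall: float
    n_samples: int
    degenerate: bool = False  # no positives predicted nor present


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> MetricSet:
    """Accuracy, precision, recall and F1 with positive label = symptom
    present. Empty input is an error; an input with no positive labels and
    no positive predictions reports F1 = 0 with the degenerate flag."""
    y_pred = np.asarray(predictions, dtype=int)
    y_true = np.asarray(labels, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels are not aligned")
    tp = int(np.count_nonzero((y_pred == 1) & (y_true == 1)))
    fp = int(np.count_nonzero((y_pred == 1) & (y_true == 0)))
    fn = int(np.count_nonzero((y_pred == 0) & (y_true == 1)))
    accuracy = float(np.mean(y_pred == y_true))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MetricSet(
        accuracy=accuracy,
        f1=f1,
        precision=precision,
        recall=recall,
        n_samples=int(y_true.size),
        degenerate=(tp + fp + fn) == 0,
    )


# --------------------------------------------------------------------------
# hierarchical paired bootstrap
# --------------------------------------------------------------------------
@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    ci_acc_diff: tuple[float, float]
    ci_f1_diff: tuple[float, float]
    significant_acc: bool
    significant_f1: bool
    point_acc_diff: float
    point_f1_diff: float
    n_iterations: int
    seed: int


def bootstrap_paired_diff(
    preds_a: np.ndarray,
    preds_b: np.ndarray,
    labels: np.ndarray,
    participants: np.ndarray,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    model_a: str = "A",
    model_b: str = "B",
    hierarchical: bool = True,
) -> ComparisonResult:
    """Percentile CI of paired accuracy/F1 differences (A minus B).

    All arrays are aligned over the shared (participant, period) sample
    set. Each iteration draws participants with replacement and, in the
    hierarchical (default) mode, then draws each selected participant's
    prediction periods with replacement; the identical resampled index set
    is applied to both models. ``hierarchical=False`` resamples the
    (participant, period) tuples directly."""
    preds_a = np.asarray(preds_a, dtype=int)
    preds_b = np.asarray(preds_b, dtype=int)
    labels = np.asarray(labels, dtype=int)
    participants = np.asarray(participants)
    n = labels.size
    if n == 0:
        raise ValueError("empty sample intersection")
    if not (preds_a.size == preds_b.size == participants.size == n):
        raise ValueError("inputs are not aligned")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is very small for percentile CIs", stacklevel=2)

    rng = np.random.default_rng(seed)
    ok_a = (preds_a == labels).astype(np.int64)
    ok_b = (preds_b == labels).astype(np.int64)
    uniq, inverse = np.unique(participants, return_inverse=True)
    rows_by_pid = [np.flatnonzero(inverse == i) for i in range(uniq.size)]

    acc_diffs = np.empty(n_iter)
    f1_diffs = np.empty(n_iter)
    for it in range(n_iter):
        if hierarchical:
            drawn = rng.integers(0, uniq.size, size=uniq.size)
            parts = []
            for g in drawn:
                rows = rows_by_pid[g]
                parts.append(rows[rng.integers(0, rows.size, size=rows.size)])
            idx = np.concatenate(parts)
        else:
            idx = rng.integers(0, n, size=n)
        acc_diffs[it] = (ok_a[idx].mean() - ok_b[idx].mean())
        f1_diffs[it] = f1_score_binary(labels[idx], preds_a[idx]) - f1_score_binary(
            labels[idx], preds_b[idx]
        )

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_acc = (float(np.percentile(acc_diffs, lo)), float(np.percentile(acc_diffs, hi)))
    ci_f1 = (float(np.percentile(f1_diffs, lo)), float(np.percentile(f1_diffs, hi)))
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        ci_acc_diff=ci_acc,
        ci_f1_diff=ci_f1,
        significant_acc=ci_acc[0] > 0 or ci_acc[1] < 0,
        significant_f1=ci_f1[0] > 0 or ci_f1[1] < 0,
        point_acc_diff=float(ok_a.mean() - ok_b.mean()),
        point_f1_diff=f1_score_binary(labels, preds_a) - f1_score_binary(labels, preds_b),
        n_iterations=n_iter,
        seed=seed,
    )


# --------------------------------------------------------------------------
# parsimony selection
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ParsimonyScore:
    """Data-requirement burden, ordered lexicographically: EMA burden
    (none < presurvey < average), then context burden (action-only <
    action+context), then sensor count."""

    ema_burden: int
    context_burden: int
    n_sensors: int

    @classmethod
    def from_config(cls, ema_mode: str, variant: str, n_sensors: int) -> "ParsimonyScore":
        ema_rank = {"none": 0, "presurvey": 1, "average": 2}[ema_mode]
        ctx_rank = {"action_only": 0, "action_context": 1}[variant]
        return cls(ema_rank, ctx_rank, n_sensors)

    def key(self) -> tuple[int, int, int]:
        return (self.ema_burden, self.context_burden, self.n_sensors)


def _statistically_better(res: ComparisonResult) -> str | None:
    """Which model, if either, is statistically better under the
    both-metric rule: a CI excluding 0 in its favor on >= 1 metric and no
    CI excluding 0 against it on the other."""
    a_acc = res.ci_acc_diff[0] > 0
    b_acc = res.ci_acc_diff[1] < 0
    a_f1 = res.ci_f1_diff[0] > 0
    b_f1 = res.ci_f1_diff[1] < 0
    if (a_acc or a_f1) and not (b_acc or b_f1):
        return res.model_a
    if (b_acc or b_f1) and not (a_acc or a_f1):
        return res.model_b
    return None


def pairwise_winner(
    res: ComparisonResult, parsimony: dict[str, ParsimonyScore]
) -> str | None:
    """The statistically better model, else the more parsimonious one;
    None only if parsimony also ties."""
    better = _statistically_better(res)
    if better is not None:
        return better
    ka = parsimony[res.model_a].key()
    kb = parsimony[res.model_b].key()
    if ka == kb:
        return None
    return res.model_a if ka < kb else res.model_b


def select_preferred(
    pairwise_results: list[ComparisonResult],
    parsimony: dict[str, ParsimonyScore],
    metrics: dict[str, MetricSet] | None = None,
) -> str:
    """The overall preferred model: the one never beaten in any pairwise
    comparison under the statistical-better-else-parsimony relation.

    All unordered pairs of the models must be present. If the relation is
    cyclic (no model unbeaten), falls back to the lowest parsimony score
    among Pareto-best performers on (accuracy, F1), which is logged."""
    model_ids = sorted(parsimony)
    seen_pairs = {frozenset((r.model_a, r.model_b)) for r in pairwise_results}
    expected = {frozenset(p) for p in itertools.combinations(model_ids, 2)}
    missing = expected - seen_pairs
    if missing:
        raise ValueError(f"missing pairwise comparisons: {sorted(map(sorted, missing))}")

    beaten: set[str] = set()
    for res in pairwise_results:
        w = pairwise_winner(res, parsimony)
        if w is not None:
            beaten.add(res.model_b if w == res.model_a else res.model_a)
    unbeaten = [m for m in model_ids if m not in beaten]
    if unbeaten:
        return min(unbeaten, key=lambda m: (parsimony[m].key(), m))

    log.info("pairwise preference relation is cyclic; falling back to parsimony")
    pool = model_ids
    if metrics:
        pool = [
            m
            for m in model_ids
            if not any(
                metrics[o].accuracy >= metrics[m].accuracy
                and metrics[o].f1 >= metrics[m].f1
                and (metrics[o].accuracy > metrics[m].accuracy or metrics[o].f1 > metrics[m].f1)
                for o in model_ids
                if o != m
            )
        ]
    return min(pool, key=lambda m: (parsimony[m].key(), m))
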