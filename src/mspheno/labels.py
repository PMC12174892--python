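"""Questionnaire scoring, dichotomization, and the survey schedule.

Each outcome is assessed by one instrument whose total is the plain sum of
its item (or component) scores. Totals are dichotomized into binary
severity labels at fixed thresholds (PHQ-9 >= 5, MSRS-R >= 6.4,
MFIS-5 >= 8, PSQI >= 9); a helper computes dataset-median thresholds for
the two instruments whose cutoffs were derived from the data rather than
from consensus. Surveys run on a Saturday-anchored calendar: the anchor is
the first Saturday strictly after enrollment, and administration k of an
outcome with period length P weeks falls on anchor + k*P weeks.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_PERIOD_WEEKS,
    INSTRUMENT_BY_OUTCOME,
    INSTRUMENT_ITEMS,
    OUTCOMES,
    SEVERITY_THRESHOLDS,
)


def first_saturday_after(date: dt.date) -> dt.date:
    """The first Saturday strictly after ``date`` (a Saturday maps to the
    following Saturday, not itself)."""
    days_ahead = (5 - date.weekday()) % 7  # Monday=0 ... Saturday=5
    if days_ahead == 0:
        days_ahead = 7
    return date + dt.timedelta(days=days_ahead)


def score_instrument(items: Iterable[float], instrument: str) -> float:
    """Sum item/component scores into the instrument total, validating the
    item count and per-item range."""
    if instrument not in INSTRUMENT_ITEMS:
        raise ValueError(f"unknown instrument {instrument!r}")
    n_items, item_max = INSTRUMENT_ITEMS[instrument]
    items = list(items)
    if len(items) != n_items:
        raise ValueError(
            f"{instrument} expects {n_items} items, got {len(items)}"
        )
    for idx, score in enumerate(items, 1):
        if not (0 <= score <= item_max):
            raise ValueError(
                f"{instrument} item {idx} score {score} outside [0, {item_max}]"
            )
    return float(sum(items))


def dichotomize(
    total: float, outcome: str, threshold_override: float | None = None
) -> int:
    """Binary severity label: 1 iff total >= the outcome's threshold."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    thr = SEVERITY_THRESHOLDS[outcome] if threshold_override is None else threshold_override
    return int(total >= thr)


def median_threshold(totals: Iterable[float]) -> float:
    """Dataset-median threshold, for outcomes whose cutoff is defined as the
    median total score in the cohort rather than a consensus value."""
    arr = np.asarray(list(totals), dtype=float)
    if arr.size == 0:
        raise ValueError("no totals to take a median of")
    return float(np.median(arr))


def build_schedule(
    enrollment_dates: Mapping[str, dt.date],
    n_weeks: int,
    period_len_weeks_by_outcome: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-outcome survey calendar.

    Returns one row per (participant, outcome, period_index) with the
    survey date (the Saturday closing that period) and the period's first
    day. Depression surveys run every 2 weeks, the rest every 4.
    """
    if n_weeks % 4 != 0 or n_weeks <= 0:
        raise ValueError("n_weeks must be a positive multiple of 4")
    period_weeks = dict(period_len_weeks_by_outcome or DEFAULT_PERIOD_WEEKS)
    rows = []
    for pid, enrolled in enrollment_dates.items():
        anchor = first_saturday_after(enrolled)
        for outcome in OUTCOMES:
            weeks = period_weeks[outcome]
            for k in range(1, n_weeks // weeks + 1):
                survey = anchor + dt.timedelta(weeks=weeks * k)
                start = anchor + dt.timedelta(weeks=weeks * (k - 1))
                rows.append((pid, outcome, k, start, survey))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "outcome", "period_index", "period_start", "survey_date"],
    )


def build_labels(
    questionnaires: pd.DataFrame,
    schedule: pd.DataFrame,
    threshold_overrides: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Score item-level questionnaire responses and attach binary labels.

    ``questionnaires`` is the item-level table
    (participant_id, date, instrument, item_id, score); rows are matched to
    the schedule by participant, instrument and survey date. Returns
    (participant_id, outcome, period_index, survey_date, total, label).
    """
    overrides = dict(threshold_overrides or {})
    totals = (
        questionnaires.groupby(["participant_id", "date", "instrument"], as_index=False)[
            "score"
        ]
        .sum()
        .rename(columns={"score": "total"})
    )
    # validate against the instrument's admissible range
    for rec in totals.itertuples(index=False):
        n_items, item_max = INSTRUMENT_ITEMS[rec.instrument]
        if not (0 <= rec.total <= n_items * item_max):
            raise ValueError(
                f"{rec.instrument} total {rec.total} outside [0, {n_items * item_max}]"
            )
    totals["outcome"] = totals["instrument"].map(
        {v: k for k, v in INSTRUMENT_BY_OUTCOME.items()}
    )
    sched = schedule.copy()
    sched["date"] = sched["survey_date"].map(lambda d: d.isoformat())
    merged = sched.merge(
        totals, on=["participant_id", "outcome", "date"], how="inner"
    )
    merged["label"] = [
        dichotomize(t, o, overrides.get(o))
        for t, o in zip(merged["total"], merged["outcome"])
    ]
    return merged[
        ["participant_id", "outcome", "period_index", "survey_date", "total", "label"]
    ].sort_values(["outcome", "participant_id", "period_index"], ignore_index=True)
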