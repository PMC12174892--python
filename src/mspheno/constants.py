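"""Shared vocabulary for the digital-phenotyping pipeline.

Four patient-reported outcomes are tracked, each measured by one validated
questionnaire and dichotomized at a fixed severity threshold:

========== ========== ============== =========== ==============
outcome    instrument item structure total range threshold (>=)
========== ========== ============== =========== ==============
depression PHQ9       9 items 0-3    0-27        5
ms_burden  MSRSR      8 domains 0-4  0-32        6.4
fatigue    MFIS5      5 items 0-4    0-20        8
sleep      PSQI       7 components   0-21        9
========== ========== ============== =========== ==============

Six passive sensor streams are collected (three smartphone, three fitness
tracker), plus a 2-question EMA (0-4 Likert) prompted three times a day.
"""

from __future__ import annotations

OUTCOMES: tuple[str, ...] = ("depression", "ms_burden", "fatigue", "sleep")

SENSORS: tuple[str, ...] = (
    "calls",
    "heart_rate",
    "location",
    "screen",
    "sleep",
    "steps",
)

EMA_QUESTIONS: tuple[str, ...] = ("depressed", "tired")

INSTRUMENT_BY_OUTCOME: dict[str, str] = {
    "depression": "PHQ9",
    "ms_burden": "MSRSR",
    "fatigue": "MFIS5",
    "sleep": "PSQI",
}

OUTCOME_BY_INSTRUMENT: dict[str, str] = {
    v: k for k, v in INSTRUMENT_BY_OUTCOME.items()
}

#: (n_items, per-item max) for each instrument.
INSTRUMENT_ITEMS: dict[str, tuple[int, int]] = {
    "PHQ9": (9, 3),
    "MSRSR": (8, 4),
    "MFIS5": (5, 4),
    "PSQI": (7, 3),
}

#: Dichotomization thresholds (label = 1 iff total >= threshold).
SEVERITY_THRESHOLDS: dict[str, float] = {
    "depression": 5.0,
    "ms_burden": 6.4,
    "fatigue": 8.0,
    "sleep": 9.0,
}

#: Prediction-period length in weeks: depressive symptoms are assessed every
#: 2 weeks, the other outcomes every 4 weeks.
DEFAULT_PERIOD_WEEKS: dict[str, int] = {
    "depression": 2,
    "ms_burden": 4,
    "fatigue": 4,
    "sleep": 4,
}

#: Day epochs on the participant-local clock, half-open [start_hour, end_hour).
EPOCH_HOURS: dict[str, tuple[int, int]] = {
    "night": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 18),
    "evening": (18, 24),
}

EPOCHS: tuple[str, ...] = ("all_day", "night", "morning", "afternoon", "evening")
DAY_GROUPS: tuple[str, ...] = ("all_days", "weekdays", "weekends")

#: EMA prompt times (local clock).
EMA_PROMPT_HOURS: tuple[int, ...] = (9, 14, 19)

#: Behavior channels the generator can shift with latent symptom severity.
BEHAVIOR_CHANNELS: tuple[str, ...] = (
    "steps",
    "home_time",
    "screen_session",
    "sleep_efficiency",
    "awakenings",
    "heart_rate",
    "calls",
)
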