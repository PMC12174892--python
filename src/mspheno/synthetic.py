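"""Synthetic cohort generator for the digital-phenotyping pipeline.

Emulates the data a longitudinal passive-sensing study of people with MS
produces: six raw sensor streams per participant (calls, heart rate,
location, screen use, sleep state, steps), thrice-daily 2-question EMAs,
and periodic symptom questionnaires — together with the ground-truth latent
symptom severities that drive them, so that every downstream stage of the
pipeline can be tested for signal recovery and leakage without access to
any real cohort.

The generative model, per participant:

* A participant-level baseline severity per outcome (normal, sd
  ``baseline_sd``) plus an AR(1) period-level fluctuation (persistence
  ``ar1_rho``, innovation sd ``innovation_sd``) gives one latent severity
  per (outcome, period) on a z-like scale.
* Each day, behavior channels (daily steps, home-time fraction, mean
  screen-session length, sleep efficiency, awakenings, resting heart rate,
  call count) are drawn around participant baselines, shifted by
  ``effect_sizes[(outcome, channel)] * severity * channel_day_sd`` and the
  raw minute/event-level streams are rendered from them.
* Questionnaire item scores are constructed so the instrument total crosses
  the dichotomization threshold exactly when the period's latent severity
  crosses the configured latent cut: ground-truth binary labels are
  recoverable from the questionnaires by definition.
* Missingness is MCAR at whole (sensor, participant, day) granularity, and
  EMA prompts are answered with probability ``ema_compliance``.

All timestamps are participant-local naive datetimes; days run midnight to
midnight. Regeneration with the same config (including seed) is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import (
    BEHAVIOR_CHANNELS,
    DEFAULT_PERIOD_WEEKS,
    EMA_PROMPT_HOURS,
    EMA_QUESTIONS,
    INSTRUMENT_BY_OUTCOME,
    INSTRUMENT_ITEMS,
    OUTCOMES,
    SENSORS,
    SEVERITY_THRESHOLDS,
)
from .labels import first_saturday_after

# --------------------------------------------------------------------------
# channel calibration: (population base, between-day sd) in natural units
# --------------------------------------------------------------------------
CHANNEL_BASE: dict[str, float] = {
    "steps": 7000.0,
    "home_time": 0.55,
    "screen_session": 5.0,
    "sleep_efficiency": 0.88,
    "awakenings": 2.0,
    "heart_rate": 72.0,
    "calls": 6.0,
}
CHANNEL_DAY_SD: dict[str, float] = {
    "steps": 2000.0,
    "home_time": 0.15,
    "screen_session": 2.0,
    "sleep_efficiency": 0.05,
    "awakenings": 1.5,
    "heart_rate": 5.0,
    "calls": 2.5,
}

#: Moderate default severity->behavior couplings (standardized shift of the
#: channel per unit latent severity). Signs follow the expected direction:
#: worse depression -> fewer steps, more time at home, longer screen
#: sessions, fewer calls; worse sleep -> lower efficiency, more awakenings.
DEFAULT_EFFECT_SIZES: dict[tuple[str, str], float] = {
    ("depression", "steps"): -0.5,
    ("depression", "home_time"): 0.5,
    ("depression", "screen_session"): 0.3,
    ("depression", "calls"): -0.3,
    ("ms_burden", "steps"): -0.6,
    ("ms_burden", "home_time"): 0.4,
    ("ms_burden", "heart_rate"): -0.2,
    ("fatigue", "steps"): -0.5,
    ("fatigue", "heart_rate"): -0.3,
    ("fatigue", "screen_session"): 0.2,
    ("sleep", "sleep_efficiency"): -0.6,
    ("sleep", "awakenings"): 0.6,
    ("sleep", "steps"): -0.2,
}


def null_effect_sizes() -> dict[tuple[str, str], float]:
    """Zero coupling everywhere: behavior carries no symptom signal."""
    return {}


def planted_effect_sizes(outcome: str = "depression") -> dict[tuple[str, str], float]:
    """Strong (>= 1 sd) couplings of one outcome's severity to steps, sleep
    efficiency and home time, used for signal-recovery experiments.

    Effects are planted for a single outcome so the recovery experiment is
    not confounded by the other outcomes' independent severities shifting
    the same behavior channels."""
    return {
        (outcome, "steps"): -1.0,
        (outcome, "sleep_efficiency"): -1.0,
        (outcome, "home_time"): 1.0,
        (outcome, "screen_session"): 0.5,
        (outcome, "calls"): -0.5,
    }


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class CohortConfig:
    """Everything needed to regenerate a synthetic cohort bit-identically."""

    n_participants: int = 20
    n_weeks: int = 12
    seed: int = 0
    period_len_weeks_by_outcome: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_WEEKS)
    )
    ar1_rho: dict[str, float] = field(
        default_factory=lambda: {o: 0.6 for o in OUTCOMES}
    )
    baseline_sd: float = 1.0
    innovation_sd: float = 0.8
    effect_sizes: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    target_prevalence: dict[str, float] = field(
        default_factory=lambda: {o: 0.5 for o in OUTCOMES}
    )
    ema_compliance: float = 0.8
    missing_day_rate: float = 0.1
    ema_noise_sd: float = 0.6
    #: Coupling of EMA responses to same-day latent severity (Likert points
    #: per severity sd). EMAs are active self-reports, so this is separate
    #: from the passive behavior effect sizes; set to 0 for a fully null
    #: cohort in which nothing observable carries symptom signal.
    ema_signal: float = 0.9
    tie_side: str = "positive"  # label at exactly the latent cut
    start_date: dt.date = dt.date(2019, 11, 18)
    mnar_strength: float = 0.0  # >0 links sensor missingness to severity
    timezone: str = "local"  # naive participant-local clock; no DST

    def __post_init__(self) -> None:
        if self.n_participants < 10:
            raise ValueError("n_participants must be >= 10 (leave-5-out CV)")
        if self.n_weeks % 4 != 0 or self.n_weeks < 4:
            raise ValueError("n_weeks must be a positive multiple of 4")
        for o, rho in self.ar1_rho.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"ar1_rho[{o}]={rho} outside [0, 1)")
        for name, p in (
            ("ema_compliance", self.ema_compliance),
            ("missing_day_rate", self.missing_day_rate),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        for o, p in self.target_prevalence.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"target_prevalence[{o}]={p} outside (0, 1)")
        for o, w in self.period_len_weeks_by_outcome.items():
            if w not in (2, 4):
                raise ValueError(f"period length for {o} must be 2 or 4 weeks")
        for (o, c) in self.effect_sizes:
            if o not in OUTCOMES or c not in BEHAVIOR_CHANNELS:
                raise ValueError(f"unknown effect-size key ({o}, {c})")
        if self.tie_side not in ("positive", "negative"):
            raise ValueError("tie_side must be 'positive' or 'negative'")

    # latent marginal sd combines the participant baseline and the
    # stationary AR(1) fluctuation
    @property
    def latent_marginal_sd(self) -> dict[str, float]:
        out = {}
        for o in OUTCOMES:
            rho = self.ar1_rho[o]
            stat_var = self.innovation_sd**2 / (1.0 - rho**2)
            out[o] = math.sqrt(self.baseline_sd**2 + stat_var)
        return out

    @property
    def latent_cut(self) -> dict[str, float]:
        """Severity cut per outcome chosen so the marginal positive-label
        probability equals ``target_prevalence``."""
        return {
            o: float(norm.ppf(1.0 - self.target_prevalence[o])) * sd
            for o, sd in self.latent_marginal_sd.items()
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_sizes"] = {f"{o}.{c}": v for (o, c), v in self.effect_sizes.items()}
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "effect_sizes" in d:
            d["effect_sizes"] = {
                tuple(k.split(".", 1)): v for k, v in d["effect_sizes"].items()
            }
        if isinstance(d.get("start_date"), str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        return cls(**d)


@dataclass
class ParticipantParams:
    """Per-participant latent baselines and geography."""

    participant_id: str
    severity_baseline: dict[str, float]
    channel_base: dict[str, float]
    home: tuple[float, float]
    work: tuple[float, float]
    errand: tuple[float, float]
    enrollment_date: dt.date

    @property
    def anchor(self) -> dt.date:
        return first_saturday_after(self.enrollment_date)


@dataclass
class GeneratedDataset:
    """A full synthetic cohort: raw streams + EMAs + questionnaires + truth."""

    config: CohortConfig
    participants: list[ParticipantParams]
    streams: dict[str, dict[str, pd.DataFrame]]  # pid -> sensor -> frame
    ema: pd.DataFrame  # participant_id, ts, question, value
    questionnaires: pd.DataFrame  # participant_id, date, instrument, item_id, score
    truth: pd.DataFrame  # participant_id, outcome, period_index, value

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def content_hash(self) -> str:
        """SHA-256 over a canonical CSV rendering of every table."""
        h = hashlib.sha256()
        for pid in sorted(self.streams):
            for sensor in SENSORS:
                h.update(self.streams[pid][sensor].to_csv(index=False).encode())
        h.update(self.ema.to_csv(index=False).encode())
        h.update(self.questionnaires.to_csv(index=False).encode())
        h.update(self.truth.to_csv(index=False).encode())
        return h.hexdigest()


# --------------------------------------------------------------------------
# latent severity
# --------------------------------------------------------------------------
def simulate_severity(
    baseline: float,
    n_periods: int,
    rho: float,
    innovation_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1) latent-severity trajectory around a participant baseline.

    The fluctuation is initialized from its stationary distribution, so the
    series is stationary with mean ``baseline``, lag-1 autocorrelation
    ``rho`` and variance ``innovation_sd**2 / (1 - rho**2)``.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho={rho} outside [0, 1)")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    e = np.empty(n_periods)
    e[0] = rng.normal(0.0, innovation_sd / math.sqrt(1.0 - rho**2))
    innov = rng.normal(0.0, innovation_sd, size=n_periods - 1)
    for t in range(1, n_periods):
        e[t] = rho * e[t - 1] + innov[t - 1]
    return baseline + e


# --------------------------------------------------------------------------
# one day of raw streams
# --------------------------------------------------------------------------
def _channel_value(
    channel: str,
    params: ParticipantParams,
    severity: dict[str, float],
    effect_sizes: dict[tuple[str, str], float],
    day_noise: float,
) -> float:
    shift = sum(
        effect_sizes.get((o, channel), 0.0) * severity[o] * CHANNEL_DAY_SD[channel]
        for o in OUTCOMES
    )
    return params.channel_base[channel] + shift + day_noise


_MINUTES = np.arange(1440)


def _activity_profile() -> np.ndarray:
    """Relative step propensity per minute of day (zero overnight)."""
    h = _MINUTES / 60.0
    w = np.zeros(1440)
    awake = (h >= 7.0) & (h < 22.5)
    w[awake] = 1.0
    # commuting / midday / evening peaks
    for center, width, amp in ((8.5, 1.0, 2.0), (12.5, 1.5, 1.5), (17.8, 1.2, 2.0)):
        w += amp * np.exp(-0.5 * ((h - center) / width) ** 2)
    w[~awake] *= 0.02
    return w


_BASE_PROFILE = _activity_profile()


def render_day(
    severity: dict[str, float],
    date: dt.date,
    params: ParticipantParams,
    config: CohortConfig,
    seed_key: tuple[int, ...],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Render one participant-day of all six sensor streams plus EMA prompts.

    ``severity`` holds the current-period latent value for all four
    outcomes. Behavior channels are shifted by the configured effect sizes;
    degenerate draws clamp to channel floors (steps >= 0, fractions in
    (0, 1)). Minute-cadence sensors emit one sample per minute of the local
    day; location emits one sample per 10 minutes.
    """
    rng = np.random.default_rng(seed_key)
    es = config.effect_sizes
    day0 = np.datetime64(pd.Timestamp(date), "s")
    is_weekend = date.weekday() >= 5

    # ---- steps ------------------------------------------------------
    total_steps = max(
        0.0, _channel_value("steps", params, severity, es, rng.normal(0, 1500.0))
    )
    profile = _BASE_PROFILE * rng.uniform(0.6, 1.4, size=1440)
    counts = rng.multinomial(int(round(total_steps)), profile / profile.sum())
    steps = pd.DataFrame(
        {"ts": day0 + _MINUTES * np.timedelta64(60, "s"), "count": counts}
    )

    # ---- heart rate -------------------------------------------------
    hr_mu = _channel_value("heart_rate", params, severity, es, rng.normal(0, 3.0))
    circadian = 6.0 * np.sin(2.0 * np.pi * (_MINUTES / 1440.0 - 0.3))
    bpm = hr_mu + circadian + 0.05 * counts + rng.normal(0, 3.0, size=1440)
    heart_rate = pd.DataFrame(
        {
            "ts": day0 + _MINUTES * np.timedelta64(60, "s"),
            "bpm": np.clip(np.round(bpm), 40, 190).astype(int),
        }
    )

    # ---- sleep ------------------------------------------------------
    eff = float(
        np.clip(
            _channel_value(
                "sleep_efficiency", params, severity, es, rng.normal(0, 0.02)
            ),
            0.40,
            0.99,
        )
    )
    n_awake = max(
        0,
        int(round(_channel_value("awakenings", params, severity, es, rng.normal(0, 0.8)))),
    )
    wake_min = int(np.clip(rng.normal(7 * 60, 25), 5 * 60, 9 * 60))
    onset_min = int(np.clip(rng.normal(23 * 60, 25), 21 * 60 + 30, 1439))
    block = np.concatenate([np.arange(0, wake_min), np.arange(onset_min, 1440)])
    state = np.full(block.size, "asleep", dtype=object)
    # awake runs of 2-6 minutes, then restless minutes to hit the target
    # efficiency = asleep / (asleep + restless + awake)
    awake_positions = rng.choice(block.size, size=min(n_awake, block.size), replace=False)
    for pos in awake_positions:
        run = int(rng.integers(2, 7))
        state[pos : pos + run] = "awake"
    n_awake_min = int((state == "awake").sum())
    n_restless = max(0, int(round(block.size * (1.0 - eff))) - n_awake_min)
    asleep_idx = np.flatnonzero(state == "asleep")
    if n_restless and asleep_idx.size:
        sel = rng.choice(asleep_idx, size=min(n_restless, asleep_idx.size), replace=False)
        state[sel] = "restless"
    unk = rng.random(block.size) < 0.01
    state[unk] = "unknown"
    sleep = pd.DataFrame(
        {"ts": day0 + block * np.timedelta64(60, "s"), "state": state}
    )

    # ---- location ---------------------------------------------------
    f_home = float(
        np.clip(
            _channel_value("home_time", params, severity, es, rng.normal(0, 0.08)),
            0.02,
            0.98,
        )
    )
    loc_minutes = np.arange(0, 1440, 10)
    centers = np.tile(params.home, (loc_minutes.size, 1))
    day_start, day_end = 8 * 60, 22 * 60  # daytime window eligible for leaving home
    away_min = (1.0 - f_home) * (day_end - day_start)
    away_from = 9 * 60 if not is_weekend else 13 * 60
    away_to = min(day_end, int(away_from + away_min))
    away_place = params.work if not is_weekend else params.errand
    in_away = (loc_minutes >= away_from) & (loc_minutes < away_to)
    centers[in_away] = away_place
    jitter = rng.normal(0.0, 0.0001, size=centers.shape)  # ~10 m gps noise
    location = pd.DataFrame(
        {
            "ts": day0 + loc_minutes * np.timedelta64(60, "s"),
            "lat": centers[:, 0] + jitter[:, 0],
            "lon": centers[:, 1] + jitter[:, 1],
        }
    )

    # ---- calls ------------------------------------------------------
    lam = max(0.2, _channel_value("calls", params, severity, es, 0.0))
    n_calls = int(rng.poisson(lam))
    call_ts = np.sort(rng.integers(8 * 3600, 21 * 3600, size=n_calls))
    direction = rng.choice(
        ["incoming", "outgoing", "missed"], size=n_calls, p=[0.45, 0.45, 0.10]
    )
    duration = np.where(
        direction == "missed", 0.0, np.round(rng.lognormal(4.6, 0.9, size=n_calls))
    )
    calls = pd.DataFrame(
        {
            "ts": day0 + call_ts * np.timedelta64(1, "s"),
            "direction": direction,
            "duration_s": duration,
        }
    )

    # ---- screen -----------------------------------------------------
    sess_mu = max(0.5, _channel_value("screen_session", params, severity, es, 0.0))
    n_sessions = int(rng.poisson(25))
    starts = np.sort(rng.integers(7 * 3600, int(23.5 * 3600), size=n_sessions))
    starts = np.unique(starts)
    lengths = rng.lognormal(math.log(sess_mu), 0.8, size=starts.size) * 60.0
    if starts.size > 1:  # sessions may not overlap the next unlock
        gaps = np.diff(starts, append=24 * 3600) - 30.0
        lengths = np.minimum(lengths, np.maximum(gaps, 30.0))
    ends = np.minimum(starts + np.round(lengths).astype(int), 24 * 3600 - 2)
    ev_ts, ev_status = [], []
    for s, e in zip(starts, ends):
        ev_ts += [s, s + 1, e, e + 1]
        ev_status += ["on", "unlock", "lock", "off"]
    screen = pd.DataFrame(
        {
            "ts": day0 + np.asarray(ev_ts, dtype=int) * np.timedelta64(1, "s"),
            "status": ev_status,
        }
    )

    # ---- EMA --------------------------------------------------------
    sev_by_question = {"depressed": severity["depression"], "tired": severity["fatigue"]}
    rows = []
    for hour in EMA_PROMPT_HOURS:
        for q in EMA_QUESTIONS:
            raw = (
                1.5
                + config.ema_signal * sev_by_question[q]
                + rng.normal(0, config.ema_noise_sd)
            )
            rows.append(
                (
                    day0 + np.timedelta64(hour * 3600, "s"),
                    q,
                    int(np.clip(round(raw), 0, 4)),
                )
            )
    ema = pd.DataFrame(rows, columns=["ts", "question", "value"])

    streams = {
        "calls": calls,
        "heart_rate": heart_rate,
        "location": location,
        "screen": screen,
        "sleep": sleep,
        "steps": steps,
    }
    return streams, ema


# --------------------------------------------------------------------------
# questionnaires
# --------------------------------------------------------------------------
def severity_to_total(
    sev: float, outcome: str, cut: float, tie_side: str = "positive"
) -> int:
    """Map a latent severity to an instrument total so that the total crosses
    the dichotomization threshold exactly when ``sev`` crosses ``cut``.

    The mapping is monotone; ties at exactly the cut go to the configured
    side (default positive).
    """
    instrument = INSTRUMENT_BY_OUTCOME[outcome]
    n_items, item_max = INSTRUMENT_ITEMS[instrument]
    max_total = n_items * item_max
    thr = SEVERITY_THRESHOLDS[outcome]
    pos_floor = math.ceil(thr)  # smallest integer total labelled positive
    neg_ceil = pos_floor - 1
    offset = sev - cut
    positive = offset > 0 or (offset == 0 and tie_side == "positive")
    scale = max_total / 6.0  # ~3 latent sd span the score range
    if positive:
        return min(max_total, pos_floor + int(round(offset * scale)))
    return max(0, neg_ceil - int(round(-offset * scale)))


def _spread_items(total: int, n_items: int, item_max: int) -> list[int]:
    """Distribute an integer total as evenly as possible across items."""
    q, r = divmod(total, n_items)
    items = [q + 1] * r + [q] * (n_items - r)
    assert all(0 <= it <= item_max for it in items)
    return items


def emit_questionnaires(
    truth: pd.DataFrame,
    participants: list[ParticipantParams],
    config: CohortConfig,
) -> pd.DataFrame:
    """Item-level questionnaire responses on the Saturday-anchored schedule.

    Each administration's total is a monotone function of the period's
    latent severity, constructed so the binary label is identifiable."""
    cuts = config.latent_cut
    anchors = {p.participant_id: p.anchor for p in participants}
    rows = []
    for rec in truth.itertuples(index=False):
        outcome = rec.outcome
        instrument = INSTRUMENT_BY_OUTCOME[outcome]
        n_items, item_max = INSTRUMENT_ITEMS[instrument]
        weeks = config.period_len_weeks_by_outcome[outcome]
        date = anchors[rec.participant_id] + dt.timedelta(
            weeks=weeks * rec.period_index
        )
        total = severity_to_total(rec.value, outcome, cuts[outcome], config.tie_side)
        for item_id, score in enumerate(_spread_items(total, n_items, item_max), 1):
            rows.append((rec.participant_id, date.isoformat(), instrument, item_id, score))
    return pd.DataFrame(
        rows, columns=["participant_id", "date", "instrument", "item_id", "score"]
    )


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------
def apply_missingness(dataset: GeneratedDataset) -> GeneratedDataset:
    """Delete whole (sensor, participant, day) cells MCAR and thin EMA
    prompts to the configured compliance; ground truth is untouched.

    With ``mnar_strength > 0`` the per-day deletion probability increases
    with that day's mean latent severity (logistic link), for robustness
    experiments; the default is plain MCAR."""
    cfg = dataset.config
    rng = np.random.default_rng([cfg.seed, 982451653])
    rate = cfg.missing_day_rate

    new_streams: dict[str, dict[str, pd.DataFrame]] = {}
    for pid in sorted(dataset.streams):
        new_streams[pid] = {}
        for sensor in SENSORS:
            frame = dataset.streams[pid][sensor]
            if frame.empty or rate == 0.0:
                new_streams[pid][sensor] = frame.copy()
                continue
            days = frame["ts"].values.astype("datetime64[D]")
            uniq = np.unique(days)
            p = np.full(uniq.size, rate)
            if cfg.mnar_strength > 0 and 0.0 < rate < 1.0:
                # shift deletion odds by participant-mean severity
                s = float(
                    dataset.truth.loc[
                        dataset.truth.participant_id == pid, "value"
                    ].mean()
                )
                logit = math.log(rate / (1 - rate)) + cfg.mnar_strength * s
                p[:] = 1.0 / (1.0 + math.exp(-logit))
            drop = uniq[rng.random(uniq.size) < p]
            keep = ~np.isin(days, drop)
            new_streams[pid][sensor] = frame.loc[keep].reset_index(drop=True)

    ema = dataset.ema
    if cfg.ema_compliance < 1.0 and not ema.empty:
        prompts = ema[["participant_id", "ts"]].drop_duplicates()
        answered = rng.random(len(prompts)) < cfg.ema_compliance
        kept = prompts.loc[answered]
        ema = ema.merge(kept, on=["participant_id", "ts"], how="inner")
    return GeneratedDataset(
        config=cfg,
        participants=dataset.participants,
        streams=new_streams,
        ema=ema.reset_index(drop=True),
        questionnaires=dataset.questionnaires,
        truth=dataset.truth,
    )


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------
def _draw_participants(config: CohortConfig) -> list[ParticipantParams]:
    out = []
    for i in range(config.n_participants):
        rng = np.random.default_rng([config.seed, 7919, i])
        pid = f"P{i + 1:03d}"
        baseline = {
            o: float(rng.normal(0.0, config.baseline_sd)) for o in OUTCOMES
        }
        base = {
            c: float(
                CHANNEL_BASE[c] + rng.normal(0.0, 0.5 * CHANNEL_DAY_SD[c])
            )
            for c in BEHAVIOR_CHANNELS
        }
        base["sleep_efficiency"] = float(np.clip(base["sleep_efficiency"], 0.6, 0.97))
        base["home_time"] = float(np.clip(base["home_time"], 0.15, 0.9))
        home = (40.44 + rng.normal(0, 0.05), -79.99 + rng.normal(0, 0.05))
        work = (home[0] + rng.normal(0, 0.03), home[1] + rng.normal(0, 0.03))
        errand = (home[0] + rng.normal(0, 0.02), home[1] + rng.normal(0, 0.02))
        enrollment = config.start_date + dt.timedelta(days=i % 7)
        out.append(
            ParticipantParams(
                participant_id=pid,
                severity_baseline=baseline,
                channel_base=base,
                home=home,
                work=work,
                errand=errand,
                enrollment_date=enrollment,
            )
        )
    return out


def generate_cohort(config: CohortConfig) -> GeneratedDataset:
    """Generate the full synthetic cohort (after missingness injection)."""
    participants = _draw_participants(config)
    n_days = config.n_weeks * 7

    truth_rows = []
    streams: dict[str, dict[str, pd.DataFrame]] = {}
    ema_frames = []
    for i, part in enumerate(participants):
        # latent severities per outcome
        sev_by_outcome: dict[str, np.ndarray] = {}
        for j, outcome in enumerate(OUTCOMES):
            weeks = config.period_len_weeks_by_outcome[outcome]
            n_periods = config.n_weeks // weeks
            rng = np.random.default_rng([config.seed, 104729, i, j])
            series = simulate_severity(
                part.severity_baseline[outcome],
                n_periods,
                config.ar1_rho[outcome],
                config.innovation_sd,
                rng,
            )
            sev_by_outcome[outcome] = series
            for k, v in enumerate(series, 1):
                truth_rows.append((part.participant_id, outcome, k, float(v)))

        day_frames: dict[str, list[pd.DataFrame]] = {s: [] for s in SENSORS}
        ema_days = []
        anchor = part.anchor
        for d in range(n_days):
            date = anchor + dt.timedelta(days=d)
            severity = {
                o: float(
                    sev_by_outcome[o][
                        d // (config.period_len_weeks_by_outcome[o] * 7)
                    ]
                )
                for o in OUTCOMES
            }
            day_streams, day_ema = render_day(
                severity, date, part, config, (config.seed, 15485863, i, d)
            )
            for s in SENSORS:
                day_frames[s].append(day_streams[s])
            ema_days.append(day_ema)
        streams[part.participant_id] = {
            s: pd.concat(day_frames[s], ignore_index=True) for s in SENSORS
        }
        ema_p = pd.concat(ema_days, ignore_index=True)
        ema_p.insert(0, "participant_id", part.participant_id)
        ema_frames.append(ema_p)

    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "outcome", "period_index", "value"]
    )
    ema = pd.concat(ema_frames, ignore_index=True)
    questionnaires = emit_questionnaires(truth, participants, config)
    dataset = GeneratedDataset(
        config=config,
        participants=participants,
        streams=streams,
        ema=ema,
        questionnaires=questionnaires,
        truth=truth,
    )
    return apply_missingness(dataset)


# --------------------------------------------------------------------------
# CSV export
# --------------------------------------------------------------------------
def write_dataset(dataset: GeneratedDataset, out_dir: str | Path) -> None:
    """Write the cohort as one CSV per (participant, sensor) plus shared
    ema/questionnaires/truth tables (UTF-8, ISO-8601 timestamps)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, sensors in dataset.streams.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for sensor, frame in sensors.items():
            frame.to_csv(pdir / f"{sensor}.csv", index=False)
    dataset.ema.to_csv(out / "ema.csv", index=False)
    dataset.questionnaires.to_csv(out / "questionnaires.csv", index=False)
    dataset.truth.to_csv(out / "truth.csv", index=False)
    enrollment = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in dataset.participants],
            "enrollment_date": [
                p.enrollment_date.isoformat() for p in dataset.participants
            ],
        }
    )
    enrollment.to_csv(out / "enrollment.csv", index=False)
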