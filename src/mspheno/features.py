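"""Behavioral feature extraction from raw sensor streams.

Every sensor's daily features are computed inside *temporal slices*: the
cross of a day epoch (all day, night 00-06, morning 06-12, afternoon 12-18,
evening 18-24, half-open on the local clock) with a day-of-week group (all
days, weekdays Mon-Fri, weekends Sat-Sun), 15 slices in total. Because a
single calendar day either belongs to a day group entirely or not at all,
daily features only have to be computed per (date, epoch); the day group
decides which dates enter a period aggregate.

Feature families per sensor:

* calls — communication: counts by direction, total/mean duration.
* heart_rate — physiology: mean/sd/min/max bpm.
* location — mobility: stay-point place count, place entropy (natural
  log), normalized entropy, home-time fraction, travelled distance,
  radius of gyration. Stay-points are runs of consecutive samples within
  50 m of the run's first point lasting >= 10 min (sampling gaps > 30 min
  break a run); stay-points within 100 m merge into places; "home" is the
  place holding the most night-epoch time over the whole study.
* screen — use: unlock/on counts, unlocked minutes, mean session length.
  A session is an unlock paired with the next lock and is attributed to
  the date and epoch of its unlock.
* sleep — rest: asleep/restless minutes, awakenings (awake runs flanked by
  sleep), efficiency = asleep / (asleep + restless + awake); "unknown"
  minutes never enter the denominator.
* steps — activity: total steps, max rolling 5-minute sum, sedentary
  bouts (>= 30 consecutive zero minutes), active bouts (>= 10 consecutive
  minutes at >= 60 steps/min).

Two EMA feature types are defined per prediction period: the *average EMA*
(mean over days of the within-day mean response per question) and the
*presurvey EMA* (the last response to each question on the day before the
questionnaire administration).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DAY_GROUPS, EMA_QUESTIONS, EPOCH_HOURS, EPOCHS, SENSORS

log = logging.getLogger(__name__)

FEATURES_BY_SENSOR: dict[str, tuple[str, ...]] = {
    "calls": ("n_incoming", "n_outgoing", "n_missed", "total_duration_s", "mean_duration_s"),
    "heart_rate": ("mean_bpm", "sd_bpm", "min_bpm", "max_bpm"),
    "location": (
        "n_places",
        "location_entropy",
        "normalized_entropy",
        "home_time_fraction",
        "total_distance_km",
        "radius_of_gyration_km",
    ),
    "screen": ("n_unlocks", "n_on_events", "total_unlocked_min", "mean_session_min"),
    "sleep": ("total_asleep_min", "total_restless_min", "n_awakenings", "efficiency"),
    "steps": ("total_steps", "max_5min_steps", "n_sedentary_bouts", "n_active_bouts"),
}

#: Additive features, for which value(all_day) = sum over the four epochs.
ADDITIVE_FEATURES: dict[str, tuple[str, ...]] = {
    "calls": ("n_incoming", "n_outgoing", "n_missed", "total_duration_s"),
    "screen": ("n_unlocks", "n_on_events", "total_unlocked_min"),
    "sleep": ("total_asleep_min", "total_restless_min"),
    "steps": ("total_steps",),
}

STAYPOINT_RADIUS_M = 50.0
CLUSTER_RADIUS_M = 100.0
STAYPOINT_MIN_MINUTES = 10.0
GAP_BREAK_MINUTES = 30.0


# --------------------------------------------------------------------------
# temporal slices
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TemporalSlice:
    epoch: str
    day_group: str

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.day_group not in DAY_GROUPS:
            raise ValueError(f"unknown day group {self.day_group!r}")

    def __str__(self) -> str:
        return f"{self.epoch}/{self.day_group}"


ALL_SLICES: tuple[TemporalSlice, ...] = tuple(
    TemporalSlice(e, g) for e in EPOCHS for g in DAY_GROUPS
)


def date_in_day_group(date: dt.date, day_group: str) -> bool:
    if day_group == "all_days":
        return True
    is_weekend = date.weekday() >= 5
    return is_weekend if day_group == "weekends" else not is_weekend


def slice_membership(timestamp: dt.datetime | pd.Timestamp, sl: TemporalSlice) -> bool:
    """True iff the (participant-local) timestamp's clock time falls in the
    slice's epoch window and its weekday in the slice's day group."""
    ts = pd.Timestamp(timestamp)
    if not date_in_day_group(ts.date(), sl.day_group):
        return False
    if sl.epoch == "all_day":
        return True
    lo, hi = EPOCH_HOURS[sl.epoch]
    return lo <= ts.hour < hi


def _epoch_of_minute(minute_of_day: np.ndarray) -> np.ndarray:
    return np.searchsorted([360, 720, 1080], minute_of_day, side="right")


_EPOCH_ORDER = ("night", "morning", "afternoon", "evening")


# --------------------------------------------------------------------------
# per-window sensor feature functions
# --------------------------------------------------------------------------
def _calls_features(direction: np.ndarray, duration: np.ndarray) -> dict[str, float]:
    n_in = int((direction == "incoming").sum())
    n_out = int((direction == "outgoing").sum())
    n_miss = int((direction == "missed").sum())
    total = float(duration.sum())
    n = direction.size
    return {
        "n_incoming": n_in,
        "n_outgoing": n_out,
        "n_missed": n_miss,
        "total_duration_s": total,
        "mean_duration_s": total / n if n else np.nan,
    }


def _heart_rate_features(bpm: np.ndarray) -> dict[str, float]:
    return {
        "mean_bpm": float(bpm.mean()),
        "sd_bpm": float(bpm.std(ddof=1)) if bpm.size > 1 else np.nan,
        "min_bpm": float(bpm.min()),
        "max_bpm": float(bpm.max()),
    }


def _runs(values: np.ndarray) -> list[tuple[int, int, object]]:
    """Run-length encode: list of (start_idx, length, value)."""
    if values.size == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    return [(int(s), int(e - s), values[s]) for s, e in zip(starts, ends)]


def _sleep_features(state: np.ndarray) -> dict[str, float]:
    asleep = int((state == "asleep").sum())
    restless = int((state == "restless").sum())
    awake = int((state == "awake").sum())
    runs = _runs(state[state != "unknown"])
    n_awakenings = sum(
        1
        for i, (_, _, v) in enumerate(runs)
        if v == "awake"
        and i > 0
        and i < len(runs) - 1
        and runs[i - 1][2] == "asleep"
        and runs[i + 1][2] == "asleep"
    )
    denom = asleep + restless + awake
    return {
        "total_asleep_min": asleep,
        "total_restless_min": restless,
        "n_awakenings": n_awakenings,
        "efficiency": asleep / denom if denom else np.nan,
    }


def _steps_features(minute: np.ndarray, count: np.ndarray) -> dict[str, float]:
    order = np.argsort(minute, kind="stable")
    minute, count = minute[order], count[order]
    total = int(count.sum())
    # rolling 5-minute sum over observed contiguous minutes
    max5 = 0
    n_sed = n_act = 0
    # split into contiguous segments (1-minute spacing)
    breaks = np.flatnonzero(np.diff(minute) != 1) + 1
    for seg in np.split(count, breaks):
        if seg.size >= 5:
            csum = np.concatenate([[0], np.cumsum(seg)])
            max5 = max(max5, int((csum[5:] - csum[:-5]).max()))
        elif seg.size:
            max5 = max(max5, int(seg.sum()))
        for _, length, zero in _runs(seg == 0):
            if zero and length >= 30:
                n_sed += 1
        for _, length, hi in _runs(seg >= 60):
            if hi and length >= 10:
                n_act += 1
    return {
        "total_steps": total,
        "max_5min_steps": max5,
        "n_sedentary_bouts": n_sed,
        "n_active_bouts": n_act,
    }


# --------------------------------------------------------------------------
# screen sessions
# --------------------------------------------------------------------------
def pair_screen_sessions(screen: pd.DataFrame) -> pd.DataFrame:
    """Sweep a screen-event stream pairing each unlock with the next lock.

    Returns (start_ts, end_ts, duration_min); an unlock with no following
    lock is dropped. Sessions are attributed downstream to the date and
    epoch of the unlock."""
    frame = screen.sort_values("ts", kind="stable")
    starts, out = [], []
    open_start = None
    for ts, status in zip(frame["ts"], frame["status"]):
        if status == "unlock":
            open_start = ts
        elif status == "lock" and open_start is not None:
            out.append((open_start, ts))
            open_start = None
    sessions = pd.DataFrame(out, columns=["start_ts", "end_ts"])
    if not sessions.empty:
        sessions["duration_min"] = (
            (sessions["end_ts"] - sessions["start_ts"]).dt.total_seconds() / 60.0
        )
    else:
        sessions["duration_min"] = pd.Series(dtype=float)
    return sessions


def _screen_features(
    status: np.ndarray, session_durations: np.ndarray
) -> dict[str, float]:
    n_sessions = session_durations.size
    return {
        "n_unlocks": int((status == "unlock").sum()),
        "n_on_events": int((status == "on").sum()),
        "total_unlocked_min": float(session_durations.sum()),
        "mean_session_min": float(session_durations.mean()) if n_sessions else np.nan,
    }


# --------------------------------------------------------------------------
# location stay-points and clusters
# --------------------------------------------------------------------------
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (array-capable)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class LocationContext:
    """Study-level stay-point/cluster structure for one participant."""

    staypoints: pd.DataFrame  # start_ts, end_ts, lat, lon, cluster
    home_cluster: int | None


def extract_staypoints(location: pd.DataFrame) -> pd.DataFrame:
    """Anchor-based stay-point extraction.

    A candidate opens at a sample and absorbs subsequent samples while they
    stay within 50 m of the anchor and within 30 min of the previous
    sample; a candidate lasting >= 10 min becomes a stay-point at the
    centroid of its members."""
    frame = location.sort_values("ts", kind="stable").reset_index(drop=True)
    ts = frame["ts"].to_numpy()
    lat = frame["lat"].to_numpy()
    lon = frame["lon"].to_numpy()
    n = len(frame)
    out = []
    i = 0
    while i < n:
        j = i + 1
        while j < n:
            gap_min = (ts[j] - ts[j - 1]) / np.timedelta64(60, "s")
            if gap_min > GAP_BREAK_MINUTES:
                break
            if haversine_km(lat[i], lon[i], lat[j], lon[j]) * 1000.0 > STAYPOINT_RADIUS_M:
                break
            j += 1
        dur_min = (ts[j - 1] - ts[i]) / np.timedelta64(60, "s")
        if dur_min >= STAYPOINT_MIN_MINUTES:
            out.append(
                (
                    ts[i],
                    ts[j - 1],
                    float(lat[i:j].mean()),
                    float(lon[i:j].mean()),
                )
            )
        i = max(j, i + 1)
    return pd.DataFrame(out, columns=["start_ts", "end_ts", "lat", "lon"])


def _cluster_staypoints(staypoints: pd.DataFrame) -> np.ndarray:
    """Greedy merge of stay-points within 100 m into places."""
    centroids: list[tuple[float, float, int]] = []  # lat, lon, count
    assignment = np.empty(len(staypoints), dtype=int)
    for idx, (la, lo) in enumerate(zip(staypoints["lat"], staypoints["lon"])):
        best = -1
        for ci, (cla, clo, _) in enumerate(centroids):
            if haversine_km(la, lo, cla, clo) * 1000.0 <= CLUSTER_RADIUS_M:
                best = ci
                break
        if best < 0:
            centroids.append((la, lo, 1))
            best = len(centroids) - 1
        else:
            cla, clo, cnt = centroids[best]
            centroids[best] = (
                (cla * cnt + la) / (cnt + 1),
                (clo * cnt + lo) / (cnt + 1),
                cnt + 1,
            )
        assignment[idx] = best
    return assignment


def _night_overlap_minutes(start: pd.Timestamp, end: pd.Timestamp) -> float:
    """Minutes of [start, end] lying in the night epoch (00:00-06:00)."""
    total = 0.0
    day = start.normalize()
    while day <= end.normalize():
        lo = max(start, day)
        hi = min(end, day + pd.Timedelta(hours=6))
        if hi > lo:
            total += (hi - lo).total_seconds() / 60.0
        day += pd.Timedelta(days=1)
    return total


def build_location_context(location: pd.DataFrame) -> LocationContext:
    sps = extract_staypoints(location)
    if sps.empty:
        return LocationContext(staypoints=sps.assign(cluster=[]), home_cluster=None)
    sps = sps.copy()
    sps["cluster"] = _cluster_staypoints(sps)
    night = {
        int(c): sum(
            _night_overlap_minutes(pd.Timestamp(s), pd.Timestamp(e))
            for s, e in zip(grp["start_ts"], grp["end_ts"])
        )
        for c, grp in sps.groupby("cluster")
    }
    home = max(night, key=night.get) if night else None
    return LocationContext(staypoints=sps, home_cluster=home)


def _staypoint_arrays(
    ctx: LocationContext,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp = ctx.staypoints
    if sp.empty:
        empty = np.array([], dtype="datetime64[s]")
        return empty, empty, np.array([], dtype=int)
    return (
        sp["start_ts"].to_numpy().astype("datetime64[s]"),
        sp["end_ts"].to_numpy().astype("datetime64[s]"),
        sp["cluster"].to_numpy(dtype=int),
    )


def _location_features_arr(
    lat: np.ndarray,
    lon: np.ndarray,
    ts: np.ndarray,
    ctx: LocationContext,
    t0: np.datetime64,
    t1: np.datetime64,
) -> dict[str, float]:
    """Array core of the mobility features for one (date, epoch) window."""
    # travelled distance over consecutive samples <= 30 min apart
    dist = 0.0
    if lat.size > 1:
        gaps = (ts[1:] - ts[:-1]) / np.timedelta64(60, "s")
        seg = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dist = float(seg[gaps <= GAP_BREAK_MINUTES].sum())
    rog = 0.0
    if lat.size:
        clat, clon = lat.mean(), lon.mean()
        rog = float(np.sqrt(np.mean(haversine_km(lat, lon, clat, clon) ** 2)))
    # stay time per place inside the window
    per_cluster: dict[int, float] = {}
    sp_start, sp_end, sp_cluster = _staypoint_arrays(ctx)
    if sp_start.size:
        lo = np.maximum(sp_start, np.datetime64(t0, "s"))
        hi = np.minimum(sp_end, np.datetime64(t1, "s"))
        overlap = (hi - lo) / np.timedelta64(60, "s")
        pos = overlap > 0
        for c, o in zip(sp_cluster[pos], overlap[pos]):
            per_cluster[int(c)] = per_cluster.get(int(c), 0.0) + float(o)
    stay_total = sum(per_cluster.values())
    n_places = len(per_cluster)
    if stay_total > 0:
        p = np.array(list(per_cluster.values())) / stay_total
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = np.nan
    norm_entropy = (
        entropy / np.log(n_places) if n_places > 1 and stay_total > 0 else (0.0 if n_places == 1 else np.nan)
    )
    home_frac = (
        per_cluster.get(ctx.home_cluster, 0.0) / stay_total
        if stay_total > 0 and ctx.home_cluster is not None
        else np.nan
    )
    return {
        "n_places": n_places,
        "location_entropy": entropy,
        "normalized_entropy": norm_entropy,
        "home_time_fraction": home_frac,
        "total_distance_km": dist,
        "radius_of_gyration_km": rog,
    }


# --------------------------------------------------------------------------
# record validation
# --------------------------------------------------------------------------
def _validate(stream: pd.DataFrame, sensor: str) -> pd.DataFrame:
    """Drop malformed records (negative durations, non-positive bpm, bad
    enums), logging what was skipped."""
    ok = pd.Series(True, index=stream.index)
    if sensor == "calls":
        ok &= stream["duration_s"] >= 0
        ok &= stream["direction"].isin(["incoming", "outgoing", "missed"])
    elif sensor == "heart_rate":
        ok &= stream["bpm"] > 0
    elif sensor == "sleep":
        ok &= stream["state"].isin(["asleep", "awake", "restless", "unknown"])
    elif sensor == "screen":
        ok &= stream["status"].isin(["on", "off", "lock", "unlock"])
    elif sensor == "steps":
        ok &= stream["count"] >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: skipped %d malformed records", sensor, n_bad)
        return stream.loc[ok]
    return stream


# --------------------------------------------------------------------------
# daily features (single-window op and cohort bulk path)
# --------------------------------------------------------------------------
@dataclass
class DailyFeatureVector:
    participant_id: str | None
    date: dt.date
    sensor: str
    slice: TemporalSlice
    values: dict[str, float]
    valid: bool


def _window_bounds(date: dt.date, epoch: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    base = pd.Timestamp(date)
    if epoch == "all_day":
        return base, base + pd.Timedelta(days=1)
    lo, hi = EPOCH_HOURS[epoch]
    return base + pd.Timedelta(hours=lo), base + pd.Timedelta(hours=hi)


def extract_daily(
    stream: pd.DataFrame,
    sensor: str,
    sl: TemporalSlice,
    date: dt.date,
    *,
    participant_id: str | None = None,
    location_context: LocationContext | None = None,
    screen_sessions: pd.DataFrame | None = None,
) -> DailyFeatureVector:
    """Daily features for one (sensor, slice, date) from a one-participant
    stream. Records outside [date, date+1) are ignored; ``valid`` is False
    (all values missing) when no data falls in the slice that day.

    For location and screen, study-level context (stay-point clusters and
    paired sessions) may be passed in; otherwise it is built from the
    given stream.
    """
    if sensor not in SENSORS:
        raise ValueError(f"unknown sensor {sensor!r}")
    missing = DailyFeatureVector(
        participant_id,
        date,
        sensor,
        sl,
        {f: np.nan for f in FEATURES_BY_SENSOR[sensor]},
        valid=False,
    )
    if not date_in_day_group(date, sl.day_group):
        return missing
    stream = _validate(stream, sensor)
    t0, t1 = _window_bounds(date, sl.epoch)
    in_win = stream.loc[(stream["ts"] >= t0) & (stream["ts"] < t1)]

    if sensor == "calls":
        if in_win.empty:
            return missing
        values = _calls_features(
            in_win["direction"].to_numpy(), in_win["duration_s"].to_numpy(dtype=float)
        )
    elif sensor == "heart_rate":
        if in_win.empty:
            return missing
        values = _heart_rate_features(in_win["bpm"].to_numpy(dtype=float))
    elif sensor == "sleep":
        if in_win.empty:
            return missing
        values = _sleep_features(in_win["state"].to_numpy())
    elif sensor == "steps":
        if in_win.empty:
            return missing
        minute = (
            in_win["ts"].dt.hour.to_numpy() * 60 + in_win["ts"].dt.minute.to_numpy()
        )
        values = _steps_features(minute, in_win["count"].to_numpy(dtype=float))
    elif sensor == "screen":
        sessions = (
            screen_sessions if screen_sessions is not None else pair_screen_sessions(stream)
        )
        in_sess = (
            sessions.loc[(sessions["start_ts"] >= t0) & (sessions["start_ts"] < t1)]
            if not sessions.empty
            else sessions
        )
        if in_win.empty and in_sess.empty:
            return missing
        values = _screen_features(
            in_win["status"].to_numpy(), in_sess["duration_min"].to_numpy(dtype=float)
        )
    else:  # location
        ctx = location_context if location_context is not None else build_location_context(stream)
        if in_win.empty:
            return missing
        values = _location_features_arr(
            in_win["lat"].to_numpy(),
            in_win["lon"].to_numpy(),
            in_win["ts"].to_numpy().astype("datetime64[s]"),
            ctx,
            np.datetime64(t0, "s"),
            np.datetime64(t1, "s"),
        )
    return DailyFeatureVector(participant_id, date, sensor, sl, values, valid=True)


_EPOCH_MINUTE_CUTS = (0, 360, 720, 1080, 1440)


def _sorted_day_arrays(frame: pd.DataFrame):
    """Sort a stream by timestamp and split it per calendar day.

    Yields (date, slice) over the sorted positional arrays, along with the
    sorted minute-of-day array for epoch slicing."""
    f = frame.sort_values("ts", kind="stable")
    ts64 = f["ts"].to_numpy().astype("datetime64[s]")
    day64 = ts64.astype("datetime64[D]")
    minute = ((ts64 - day64) / np.timedelta64(60, "s")).astype(np.int64)
    uniq, starts = np.unique(day64, return_index=True)
    bounds = np.append(starts, len(f))
    return f, ts64, day64, minute, uniq, bounds


def _emit(rows: list, date, epoch: str, sensor: str, values: dict) -> None:
    for feat, val in values.items():
        rows.append((date, epoch, sensor, feat, val))


def _bulk_event_aggregates(frame: pd.DataFrame, value_cols: dict[str, np.ndarray]):
    """Group event-level boolean/value columns by (date, epoch) and by date
    (= all_day); yields (date, epoch, aggregate-record) pairs."""
    ts64 = frame["ts"].to_numpy().astype("datetime64[s]")
    day64 = ts64.astype("datetime64[D]")
    minute = ((ts64 - day64) / np.timedelta64(60, "s")).astype(np.int64)
    epoch = np.take(_EPOCH_ORDER, _epoch_of_minute(minute))
    df = pd.DataFrame({"date": day64, "epoch": epoch} | value_cols)
    return df


def compute_daily_features(
    streams: dict[str, pd.DataFrame], participant_id: str | None = None
) -> pd.DataFrame:
    """All daily features for one participant, per (date, epoch).

    Returns a long frame (date, epoch, sensor, feature, value); a
    (date, epoch, sensor) cell appears only if the sensor has data in that
    window (the ``valid`` notion of the single-window op). Day-group
    expansion into the 15 slices happens at period aggregation.
    """
    rows: list[tuple] = []

    # ---- calls (event aggregation) ----------------------------------
    calls = _validate(streams["calls"], "calls")
    if not calls.empty:
        d = calls["direction"].to_numpy()
        df = _bulk_event_aggregates(
            calls,
            {
                "inc": d == "incoming",
                "out": d == "outgoing",
                "mis": d == "missed",
                "dur": calls["duration_s"].to_numpy(dtype=float),
            },
        )
        for keys in (["date", "epoch"], ["date"]):
            agg = df.groupby(keys, sort=True).agg(
                n=("dur", "size"),
                n_incoming=("inc", "sum"),
                n_outgoing=("out", "sum"),
                n_missed=("mis", "sum"),
                total_duration_s=("dur", "sum"),
            )
            agg["mean_duration_s"] = agg["total_duration_s"] / agg["n"]
            for idx, rec in agg.iterrows():
                date, epoch = idx if len(keys) == 2 else (idx, "all_day")
                _emit(
                    rows, date, epoch, "calls",
                    {f: rec[f] for f in FEATURES_BY_SENSOR["calls"]},
                )

    # ---- heart rate (sample aggregation) ----------------------------
    hr = _validate(streams["heart_rate"], "heart_rate")
    if not hr.empty:
        df = _bulk_event_aggregates(hr, {"bpm": hr["bpm"].to_numpy(dtype=float)})
        for keys in (["date", "epoch"], ["date"]):
            agg = df.groupby(keys, sort=True)["bpm"].agg(
                mean_bpm="mean", sd_bpm="std", min_bpm="min", max_bpm="max"
            )
            for idx, rec in agg.iterrows():
                date, epoch = idx if len(keys) == 2 else (idx, "all_day")
                _emit(
                    rows, date, epoch, "heart_rate",
                    {f: rec[f] for f in FEATURES_BY_SENSOR["heart_rate"]},
                )

    # ---- screen (event counts + paired sessions) --------------------
    screen = _validate(streams["screen"], "screen")
    if not screen.empty:
        sessions = pair_screen_sessions(screen)
        st = screen["status"].to_numpy()
        ev = _bulk_event_aggregates(
            screen, {"unlock": st == "unlock", "on": st == "on"}
        )
        if not sessions.empty:
            s64 = sessions["start_ts"].to_numpy().astype("datetime64[s]")
            sday = s64.astype("datetime64[D]")
            sminute = ((s64 - sday) / np.timedelta64(60, "s")).astype(np.int64)
            sess = pd.DataFrame(
                {
                    "date": sday,
                    "epoch": np.take(_EPOCH_ORDER, _epoch_of_minute(sminute)),
                    "dur": sessions["duration_min"].to_numpy(dtype=float),
                }
            )
        else:
            sess = pd.DataFrame({"date": [], "epoch": [], "dur": []})
        for keys in (["date", "epoch"], ["date"]):
            counts = ev.groupby(keys, sort=True).agg(
                n_unlocks=("unlock", "sum"), n_on_events=("on", "sum")
            )
            s_agg = sess.groupby(keys, sort=True)["dur"].agg(
                total_unlocked_min="sum", n_sessions="size", mean_session_min="mean"
            )
            joined = counts.join(s_agg, how="outer")
            joined[["n_unlocks", "n_on_events", "total_unlocked_min"]] = joined[
                ["n_unlocks", "n_on_events", "total_unlocked_min"]
            ].fillna(0)
            for idx, rec in joined.iterrows():
                date, epoch = idx if len(keys) == 2 else (idx, "all_day")
                _emit(
                    rows, date, epoch, "screen",
                    {f: rec[f] for f in FEATURES_BY_SENSOR["screen"]},
                )

    # ---- steps / sleep (per-day run statistics) ---------------------
    steps = _validate(streams["steps"], "steps")
    if not steps.empty:
        f, ts64, day64, minute, uniq, bounds = _sorted_day_arrays(steps)
        count = f["count"].to_numpy(dtype=float)
        for day, a, b in zip(uniq, bounds[:-1], bounds[1:]):
            date = day.item()
            m, c = minute[a:b], count[a:b]
            _emit(rows, date, "all_day", "steps", _steps_features(m, c))
            cuts = np.searchsorted(m, _EPOCH_MINUTE_CUTS)
            for ei, ep in enumerate(_EPOCH_ORDER):
                lo, hi = cuts[ei], cuts[ei + 1]
                if hi > lo:
                    _emit(rows, date, ep, "steps", _steps_features(m[lo:hi], c[lo:hi]))

    sleep = _validate(streams["sleep"], "sleep")
    if not sleep.empty:
        f, ts64, day64, minute, uniq, bounds = _sorted_day_arrays(sleep)
        state = f["state"].to_numpy()
        for day, a, b in zip(uniq, bounds[:-1], bounds[1:]):
            date = day.item()
            m, s = minute[a:b], state[a:b]
            _emit(rows, date, "all_day", "sleep", _sleep_features(s))
            cuts = np.searchsorted(m, _EPOCH_MINUTE_CUTS)
            for ei, ep in enumerate(_EPOCH_ORDER):
                lo, hi = cuts[ei], cuts[ei + 1]
                if hi > lo:
                    _emit(rows, date, ep, "sleep", _sleep_features(s[lo:hi]))

    # ---- location (stay-point context + per-window mobility) --------
    location = streams["location"]
    if not location.empty:
        ctx = build_location_context(location)
        f, ts64, day64, minute, uniq, bounds = _sorted_day_arrays(location)
        lat = f["lat"].to_numpy()
        lon = f["lon"].to_numpy()
        for day, a, b in zip(uniq, bounds[:-1], bounds[1:]):
            date = day.item()
            t0 = np.datetime64(day, "s")
            m = minute[a:b]
            _emit(
                rows, date, "all_day", "location",
                _location_features_arr(
                    lat[a:b], lon[a:b], ts64[a:b], ctx,
                    t0, t0 + np.timedelta64(86400, "s"),
                ),
            )
            cuts = np.searchsorted(m, _EPOCH_MINUTE_CUTS)
            for ei, ep in enumerate(_EPOCH_ORDER):
                lo, hi = cuts[ei], cuts[ei + 1]
                if hi > lo:
                    w0 = t0 + np.timedelta64(_EPOCH_MINUTE_CUTS[ei] * 60, "s")
                    w1 = t0 + np.timedelta64(_EPOCH_MINUTE_CUTS[ei + 1] * 60, "s")
                    _emit(
                        rows, date, ep, "location",
                        _location_features_arr(
                            lat[a + lo : a + hi], lon[a + lo : a + hi],
                            ts64[a + lo : a + hi], ctx, w0, w1,
                        ),
                    )

    out = pd.DataFrame(rows, columns=["date", "epoch", "sensor", "feature", "value"])
    if not out.empty:
        out["date"] = pd.to_datetime(out["date"]).dt.date
    if participant_id is not None:
        out.insert(0, "participant_id", participant_id)
    return out


# --------------------------------------------------------------------------
# period aggregation
# --------------------------------------------------------------------------
def feature_column(sensor: str, epoch: str, day_group: str, feature: str) -> str:
    return f"{sensor}|{epoch}|{day_group}|{feature}"


def period_columns(sensors: tuple[str, ...] = SENSORS) -> list[str]:
    """Deterministic manifest order of period feature columns."""
    cols = []
    for sensor in sensors:
        for epoch in EPOCHS:
            for dg in DAY_GROUPS:
                for feat in FEATURES_BY_SENSOR[sensor]:
                    cols.append(feature_column(sensor, epoch, dg, feat))
    return cols


def aggregate_period(
    daily: pd.DataFrame, period_start: dt.date, period_end: dt.date
) -> pd.Series:
    """Average one participant's daily features over a 2- or 4-week period,
    expanding into the 15 temporal slices.

    Mean is taken over days with data (``valid`` days) inside
    [period_start, period_end) that belong to each slice's day group; a
    feature is missing when no valid day exists. ``n_valid_days|<sensor>|
    <epoch>|<day_group>`` counters are emitted alongside.
    """
    n_days = (period_end - period_start).days
    if n_days not in (14, 28):
        raise ValueError(f"period length {n_days} days; expected 14 or 28")
    out: dict[str, float] = {}
    if daily.empty:
        window = daily
    else:
        window = daily.loc[
            (daily["date"] >= period_start) & (daily["date"] < period_end)
        ]
    for sl in ALL_SLICES:
        if window.empty:
            sub = window
        else:
            sub = window.loc[window["epoch"] == sl.epoch]
            if sl.day_group != "all_days" and not sub.empty:
                keep = sub["date"].map(lambda d: date_in_day_group(d, sl.day_group))
                sub = sub.loc[keep]
        for sensor in SENSORS:
            ssub = sub.loc[sub["sensor"] == sensor] if not sub.empty else sub
            n_valid = ssub["date"].nunique() if not ssub.empty else 0
            out[f"n_valid_days|{sensor}|{sl.epoch}|{sl.day_group}"] = n_valid
            means = (
                ssub.groupby("feature")["value"].mean() if n_valid else pd.Series(dtype=float)
            )
            for feat in FEATURES_BY_SENSOR[sensor]:
                out[feature_column(sensor, sl.epoch, sl.day_group, feat)] = float(
                    means.get(feat, np.nan)
                )
    return pd.Series(out)


def period_features_for_participant(
    daily: pd.DataFrame, periods: pd.DataFrame
) -> pd.DataFrame:
    """Wide per-period feature rows for one participant.

    ``periods`` carries (period_index, period_start, survey_date) rows; the
    period covers [period_start, survey_date). Equivalent to calling
    :func:`aggregate_period` per period but vectorized across periods via a
    single date-indexed pivot."""
    all_cols = period_columns() + [
        f"n_valid_days|{s}|{e}|{g}" for s in SENSORS for e in EPOCHS for g in DAY_GROUPS
    ]
    if daily.empty:
        out = pd.DataFrame(np.nan, index=range(len(periods)), columns=all_cols)
        for c in out.columns:
            if c.startswith("n_valid_days|"):
                out[c] = 0
        out["period_index"] = periods["period_index"].to_numpy()
        return out

    wide = daily.pivot_table(
        index="date", columns=["sensor", "epoch", "feature"], values="value",
        aggfunc="first",
    )
    validity = (
        daily.drop_duplicates(["date", "sensor", "epoch"])
        .assign(v=1)
        .pivot(index="date", columns=["sensor", "epoch"], values="v")
        .reindex(wide.index)
        .fillna(0)
        .astype(int)
    )
    dates = np.array(wide.index)
    weekday = np.array([d.weekday() for d in wide.index])
    group_masks = {
        "all_days": np.ones(dates.size, dtype=bool),
        "weekdays": weekday < 5,
        "weekends": weekday >= 5,
    }
    rows = []
    for rec in periods.itertuples(index=False):
        n_days = (rec.survey_date - rec.period_start).days
        if n_days not in (14, 28):
            raise ValueError(f"period length {n_days} days; expected 14 or 28")
        in_period = (dates >= rec.period_start) & (dates < rec.survey_date)
        out: dict[str, float] = {}
        for dg, gmask in group_masks.items():
            sel = in_period & gmask
            means = wide.loc[sel].mean(axis=0)
            counts = validity.loc[sel].sum(axis=0)
            for (sensor, epoch, feature), v in means.items():
                out[feature_column(sensor, epoch, dg, feature)] = v
            for (sensor, epoch), c in counts.items():
                out[f"n_valid_days|{sensor}|{epoch}|{dg}"] = int(c)
        out["period_index"] = rec.period_index
        rows.append(out)
    result = pd.DataFrame(rows).reindex(columns=all_cols + ["period_index"])
    for c in result.columns:
        if c.startswith("n_valid_days|"):
            result[c] = result[c].fillna(0).astype(int)
    return result


# --------------------------------------------------------------------------
# EMA features
# --------------------------------------------------------------------------
@dataclass
class EMAFeatures:
    participant_id: str | None
    period_index: int
    avg_ema: dict[str, float]
    presurvey_ema: dict[str, float]


def compute_ema_features(
    ema: pd.DataFrame,
    period_start: dt.date,
    survey_date: dt.date,
    period_index: int = 0,
    participant_id: str | None = None,
) -> EMAFeatures:
    """EMA features for one participant and one prediction period.

    The average EMA is the mean over days (with any response) of the
    within-day mean per question over [period_start, survey_date); the
    presurvey EMA is the last response per question on survey_date - 1.
    Missing values are NaN."""
    avg: dict[str, float] = {}
    pre: dict[str, float] = {}
    if ema.empty:
        return EMAFeatures(participant_id, period_index, dict.fromkeys(EMA_QUESTIONS, np.nan), dict.fromkeys(EMA_QUESTIONS, np.nan))
    frame = ema.copy()
    frame["date"] = frame["ts"].dt.date
    in_period = frame.loc[
        (frame["date"] >= period_start) & (frame["date"] < survey_date)
    ]
    presurvey_day = survey_date - dt.timedelta(days=1)
    day_before = frame.loc[frame["date"] == presurvey_day]
    for q in EMA_QUESTIONS:
        qp = in_period.loc[in_period["question"] == q]
        avg[q] = float(qp.groupby("date")["value"].mean().mean()) if len(qp) else np.nan
        qd = day_before.loc[day_before["question"] == q]
        pre[q] = float(qd.sort_values("ts")["value"].iloc[-1]) if len(qd) else np.nan
    return EMAFeatures(participant_id, period_index, avg, pre)


def daily_long_with_slices(daily: pd.DataFrame) -> pd.DataFrame:
    """Expand the per-(date, epoch) daily table into the 15-slice long form
    (participant, date, sensor, slice_epoch, slice_days, feature, value)."""
    frames = []
    for dg in DAY_GROUPS:
        if dg == "all_days":
            sub = daily
        else:
            keep = daily["date"].map(lambda d: date_in_day_group(d, dg))
            sub = daily.loc[keep]
        frames.append(sub.assign(slice_days=dg))
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"epoch": "slice_epoch"})
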