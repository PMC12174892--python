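"""Temporal slicing, per-sensor daily features, aggregation, EMA features."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mspheno as mp
from mspheno.constants import SENSORS
from mspheno.features import (
    ALL_SLICES,
    TemporalSlice,
    aggregate_period,
    compute_daily_features,
    compute_ema_features,
    extract_daily,
    feature_column,
    pair_screen_sessions,
    slice_membership,
)

TUE = dt.date(2020, 1, 7)  # a Tuesday
SAT = dt.date(2020, 1, 11)


def ts(date, h, m=0, s=0):
    return pd.Timestamp(dt.datetime(date.year, date.month, date.day, h, m, s))


class TestSliceMembership:
    def test_fifteen_distinct_slices(self):
        assert len(ALL_SLICES) == 15
        assert len(set(ALL_SLICES)) == 15

    def test_half_open_epoch_boundary(self):
        t = ts(TUE, 5, 59, 59)
        assert slice_membership(t, TemporalSlice("night", "weekdays"))
        assert not slice_membership(t, TemporalSlice("morning", "weekdays"))
        # noon belongs to the afternoon epoch
        assert slice_membership(ts(SAT, 12, 0, 0), TemporalSlice("afternoon", "weekends"))

    @settings(max_examples=300, deadline=None)
    @given(
        day=st.integers(0, 364),
        minute=st.integers(0, 1439),
        second=st.integers(0, 59),
    )
    def test_every_timestamp_in_exactly_four_slices(self, day, minute, second):
        t = pd.Timestamp("2020-01-01") + pd.Timedelta(days=day, minutes=minute, seconds=second)
        assert sum(slice_membership(t, sl) for sl in ALL_SLICES) == 4

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        stamps = pd.Timestamp("2020-01-01") + pd.to_timedelta(
            rng.integers(0, 365 * 24 * 3600, size=2000), unit="s"
        )
        for t in stamps[:200]:
            hour, wd = t.hour, t.weekday()
            for sl in ALL_SLICES:
                in_epoch = (
                    sl.epoch == "all_day"
                    or {"night": 0, "morning": 6, "afternoon": 12, "evening": 18}[sl.epoch]
                    <= hour
                    < {"night": 6, "morning": 12, "afternoon": 18, "evening": 24}[sl.epoch]
                )
                in_days = (
                    sl.day_group == "all_days"
                    or (sl.day_group == "weekends") == (wd >= 5)
                )
                assert slice_membership(t, sl) == (in_epoch and in_days)


class TestExtractDaily:
    def test_steps_sum_and_epoch_filter(self):
        stream = pd.DataFrame(
            {"ts": [ts(TUE, 10), ts(TUE, 13)], "count": [100, 200]}
        )
        v = extract_daily(stream, "steps", TemporalSlice("all_day", "all_days"), TUE)
        assert v.valid and v.values["total_steps"] == 300
        v = extract_daily(stream, "steps", TemporalSlice("morning", "all_days"), TUE)
        assert v.values["total_steps"] == 100

    def test_screen_sessions_paired_by_sweep(self):
        stream = pd.DataFrame(
            {
                "ts": [ts(TUE, 9), ts(TUE, 9, 30), ts(TUE, 20), ts(TUE, 20, 10)],
                "status": ["unlock", "lock", "unlock", "lock"],
            }
        )
        v = extract_daily(stream, "screen", TemporalSlice("all_day", "all_days"), TUE)
        assert v.values["n_unlocks"] == 2
        assert v.values["total_unlocked_min"] == pytest.approx(40.0)
        assert v.values["mean_session_min"] == pytest.approx(20.0)

    def test_day_group_mismatch_is_invalid(self):
        stream = pd.DataFrame({"ts": [ts(TUE, 10)], "count": [5]})
        v = extract_daily(stream, "steps", TemporalSlice("all_day", "weekends"), TUE)
        assert not v.valid and np.isnan(v.values["total_steps"])

    def test_out_of_window_records_never_leak(self):
        base = pd.DataFrame({"ts": [ts(TUE, 10)], "count": [100]})
        spiked = pd.concat(
            [base, pd.DataFrame({"ts": [ts(TUE + dt.timedelta(days=1), 10)], "count": [999]})],
            ignore_index=True,
        )
        sl = TemporalSlice("all_day", "all_days")
        assert (
            extract_daily(base, "steps", sl, TUE).values
            == extract_daily(spiked, "steps", sl, TUE).values
        )

    def test_sleep_awakenings_and_efficiency(self):
        minutes = ["asleep"] * 10 + ["awake"] * 2 + ["asleep"] * 5 + ["restless"] * 3 + ["unknown"]
        stream = pd.DataFrame(
            {
                "ts": [ts(TUE, 1, m) for m in range(len(minutes))],
                "state": minutes,
            }
        )
        v = extract_daily(stream, "sleep", TemporalSlice("night", "all_days"), TUE)
        assert v.values["n_awakenings"] == 1
        assert v.values["total_asleep_min"] == 15
        assert v.values["efficiency"] == pytest.approx(15 / 20)  # unknown excluded

    def test_malformed_records_skipped(self):
        stream = pd.DataFrame(
            {
                "ts": [ts(TUE, 10), ts(TUE, 11)],
                "direction": ["incoming", "sideways"],
                "duration_s": [60.0, 30.0],
            }
        )
        v = extract_daily(stream, "calls", TemporalSlice("all_day", "all_days"), TUE)
        assert v.values["n_incoming"] == 1 and v.values["total_duration_s"] == 60.0


class TestAdditivityAcrossEpochs:
    def test_epoch_partition_of_additive_features(self, small_cohort):
        pid = small_cohort.participant_ids[0]
        daily = compute_daily_features(small_cohort.streams[pid])
        from mspheno.features import ADDITIVE_FEATURES

        for sensor, feats in ADDITIVE_FEATURES.items():
            sub = daily[daily["sensor"] == sensor]
            for feat in feats:
                f = sub[sub["feature"] == feat]
                piv = f.pivot_table(index="date", columns="epoch", values="value", aggfunc="sum")
                if "all_day" not in piv:
                    continue
                epochs = [c for c in ("night", "morning", "afternoon", "evening") if c in piv]
                total = piv[epochs].fillna(0).sum(axis=1)
                np.testing.assert_allclose(
                    piv["all_day"].to_numpy(), total.to_numpy(), rtol=1e-9,
                    err_msg=f"{sensor}/{feat}",
                )


class TestAggregatePeriod:
    def _daily(self, values_by_date):
        rows = [
            (d, "all_day", "steps", "total_steps", v) for d, v in values_by_date.items()
        ]
        return pd.DataFrame(rows, columns=["date", "epoch", "sensor", "feature", "value"])

    def test_mean_over_valid_days(self):
        start = dt.date(2020, 1, 4)
        daily = self._daily({start: 300.0, start + dt.timedelta(days=1): 500.0})
        row = aggregate_period(daily, start, start + dt.timedelta(days=14))
        assert row[feature_column("steps", "all_day", "all_days", "total_steps")] == 400.0
        assert row["n_valid_days|steps|all_day|all_days"] == 2

    def test_single_valid_day_is_identity(self):
        start = dt.date(2020, 1, 4)
        daily = self._daily({start + dt.timedelta(days=3): 123.0})
        row = aggregate_period(daily, start, start + dt.timedelta(days=14))
        assert row[feature_column("steps", "all_day", "all_days", "total_steps")] == 123.0

    def test_zero_valid_days_is_missing(self):
        start = dt.date(2020, 1, 4)
        row = aggregate_period(self._daily({}), start, start + dt.timedelta(days=28))
        assert np.isnan(row[feature_column("steps", "all_day", "all_days", "total_steps")])
        assert row["n_valid_days|steps|all_day|all_days"] == 0

    def test_bad_period_length_rejected(self):
        with pytest.raises(ValueError):
            aggregate_period(self._daily({}), dt.date(2020, 1, 4), dt.date(2020, 1, 10))

    def test_day_group_restriction(self):
        start = dt.date(2020, 1, 4)  # Saturday
        daily = self._daily({start: 100.0, start + dt.timedelta(days=2): 300.0})  # Sat, Mon
        row = aggregate_period(daily, start, start + dt.timedelta(days=14))
        assert row[feature_column("steps", "all_day", "weekends", "total_steps")] == 100.0
        assert row[feature_column("steps", "all_day", "weekdays", "total_steps")] == 300.0
        assert row[feature_column("steps", "all_day", "all_days", "total_steps")] == 200.0


class TestPeriodVectorization:
    def test_fast_path_matches_single_period_reference(self, small_cohort):
        import datetime as dt

        from mspheno.features import period_features_for_participant

        pid = small_cohort.participant_ids[1]
        daily = compute_daily_features(small_cohort.streams[pid])
        start = small_cohort.participants[1].anchor
        periods = pd.DataFrame(
            {
                "period_index": [1, 2],
                "period_start": [start, start + dt.timedelta(days=14)],
                "survey_date": [
                    start + dt.timedelta(days=14),
                    start + dt.timedelta(days=28),
                ],
            }
        )
        fast = period_features_for_participant(daily, periods)
        for i, rec in enumerate(periods.itertuples(index=False)):
            ref = aggregate_period(daily, rec.period_start, rec.survey_date)
            for col, expected in ref.items():
                got = fast.iloc[i][col]
                if pd.isna(expected):
                    assert pd.isna(got), col
                else:
                    assert got == pytest.approx(expected, rel=1e-9), col


class TestEMAFeatures:
    def _ema(self, rows):
        return pd.DataFrame(rows, columns=["ts", "question", "value"])

    def test_presurvey_is_last_response_on_day_before(self):
        survey = dt.date(2020, 1, 18)
        d = survey - dt.timedelta(days=1)
        ema = self._ema(
            [(ts(d, 9), "depressed", 2), (ts(d, 14), "depressed", 3)]
        )
        f = compute_ema_features(ema, survey - dt.timedelta(days=14), survey)
        assert f.presurvey_ema["depressed"] == 3.0
        assert np.isnan(f.presurvey_ema["tired"])

    def test_presurvey_missing_without_day_before_responses(self):
        survey = dt.date(2020, 1, 18)
        ema = self._ema([(ts(survey - dt.timedelta(days=5), 9), "depressed", 4)])
        f = compute_ema_features(ema, survey - dt.timedelta(days=14), survey)
        assert np.isnan(f.presurvey_ema["depressed"])

    def test_average_is_mean_of_daily_means(self):
        survey = dt.date(2020, 1, 18)
        d1 = survey - dt.timedelta(days=10)
        d2 = survey - dt.timedelta(days=9)
        ema = self._ema(
            [
                (ts(d1, 9), "tired", 0), (ts(d1, 19), "tired", 2),  # day mean 1.0
                (ts(d2, 9), "tired", 3),  # day mean 3.0
            ]
        )
        f = compute_ema_features(ema, survey - dt.timedelta(days=14), survey)
        assert f.avg_ema["tired"] == pytest.approx(2.0)
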