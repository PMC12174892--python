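"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import pytest

import mspheno as mp
from mspheno.labels import build_labels, build_schedule
from mspheno.pipeline import RunConfig, build_feature_tables


#: Reduced hyperparameter profile for desk-scale model runs; grids and
#: inner-splits are configuration, not study conditions.
FAST_FIT = dict(C_grid=(1.0, 10.0), n_estimators_grid=(20, 50), inner_splits=2)


def fast_run_config(cohort: mp.CohortConfig, **overrides) -> RunConfig:
    kwargs = dict(FAST_FIT, cohort=cohort, n_bootstrap=1000)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort() -> mp.GeneratedDataset:
    """10 participants x 4 weeks with default effects; shared read-only."""
    return mp.generate_cohort(mp.CohortConfig(n_participants=10, n_weeks=4, seed=7))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    enr = {p.participant_id: p.enrollment_date for p in small_cohort.participants}
    schedule = build_schedule(
        enr, small_cohort.config.n_weeks, small_cohort.config.period_len_weeks_by_outcome
    )
    labels = build_labels(small_cohort.questionnaires, schedule)
    tables = build_feature_tables(small_cohort, schedule)
    return schedule, labels, tables
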