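import datetime as dt

import pytest

from steptailor import (
    DailyStepRecord,
    MessageBank,
    StepSeries,
    TailoringResponse,
    default_config_from_paper,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def bank():
    return MessageBank.default()


@pytest.fixture
def below_goal_response():
    return TailoringResponse(
        avg_daily_steps=6700, intent_6mo="yes", intent_1mo="yes"
    )


@pytest.fixture
def at_goal_response():
    return TailoringResponse(avg_daily_steps=11000, months_meeting_goal=8)


def make_series(step_values, start=dt.date(2012, 5, 7), wear=10.0,
                pid="p1"):
    """A StepSeries of consecutive days starting on a Monday."""
    return StepSeries.from_records(
        DailyStepRecord(participant_id=pid, date=start + dt.timedelta(days=i),
                        steps=s, wear_hours=wear)
        for i, s in enumerate(step_values)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One fully observed at-risk-style cohort, fixed seed, no dropout."""
    cfg = default_config_from_paper("at_risk")
    return simulate_cohort(cfg, seed=42)
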