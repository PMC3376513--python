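from datetime import date, timedelta

import pytest

from stepadvice import (
    DailyRecord,
    Intention,
    QuestionnaireResponse,
    StepLog,
    StepSummary,
    default_library,
)


def make_log(daily_steps, participant_id="p1", activities=None):
    """Build a StepLog from a list of step counts (None = unregistered day)."""
    activities = activities or {}
    records = tuple(
        DailyRecord(
            date=date(2010, 3, 1) + timedelta(days=i),
            steps=s,
            activities=tuple(activities.get(i, ())),
        )
        for i, s in enumerate(daily_steps)
    )
    return StepLog(participant_id=participant_id, records=records)


def make_response(**overrides):
    defaults = dict(
        age=45.0,
        gender="female",
        height_cm=168.0,
        weight_kg=70.0,
        baseline_step_level=8600.0,
        intention=Intention.WITHIN_1_MONTH,
    )
    defaults.update(overrides)
    return QuestionnaireResponse(**defaults)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture
def below_goal_summary():
    return StepSummary(mean_steps_per_day=8600.0, n_valid_days=7, any_truncated=False)


@pytest.fixture
def at_goal_summary():
    return StepSummary(mean_steps_per_day=11500.0, n_valid_days=7, any_truncated=False)
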