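import warnings
from fractions import Fraction as F

import pytest

from vaxavert.finite_trial import figure1_fixture
from vaxavert.trial_data import (
    IndividualRecord,
    Strategy,
    arm_incidence_from_records,
    status_table_from_records,
)


@pytest.fixture
def fig1():
    """The six-person worked-example trial (records, strategy, N)."""
    return figure1_fixture()


@pytest.fixture
def fig1_arm(fig1):
    records, strategy, _ = fig1
    return arm_incidence_from_records(records, strategy)


@pytest.fixture
def fig1_status(fig1):
    records, strategy, _ = fig1
    return status_table_from_records(records, strategy)


@pytest.fixture
def thirds_strategy():
    """Two vaccination times, 60-day intervals, one third per arm."""
    return Strategy(2, 60, (F(1, 3), F(1, 3), F(1, 3)))


def make_records(strategy, events_by_arm):
    """Build records from a per-arm list of event intervals (None = none)."""
    records = []
    for x, events in enumerate(events_by_arm):
        for i, ev in enumerate(events):
            records.append(IndividualRecord(f"a{x}s{i}", x, ev))
    return records


@pytest.fixture(autouse=True)
def _silence_empty_risk_set_warnings():
    """Degenerate allocations legitimately produce 0/0 hazards in bulk."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="empty risk set", category=RuntimeWarning
        )
        yield
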