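import datetime as dt

import pandas as pd
import pytest

from passmon.classify import ClassifierConfig, ExclusionReason, Label, LabeledInterval
from passmon.io import IntervalRecord
from passmon.simulate import FloorplanGraph, OccupantSchedule, SimConfig, generate_household


@pytest.fixture
def floorplan():
    rooms = ("bedroom", "hall", "kitchen", "living", "bath")
    return FloorplanGraph(
        rooms=rooms,
        sensors={r: (f"s_{r}",) for r in rooms},
        adjacency=(
            ("bedroom", "hall"),
            ("hall", "kitchen"),
            ("hall", "living"),
            ("living", "bath"),
        ),
        room_distance=10.0,
    )


@pytest.fixture
def schedule():
    return OccupantSchedule(
        sleep_start=dt.time(22, 0),
        sleep_end=dt.time(8, 0),
        away_bouts=((dt.time(13, 0), dt.time(14, 30)),),
        activity_bouts=((dt.time(9, 0), dt.time(10, 0), 3.0),),
    )


@pytest.fixture
def quiet_config():
    return SimConfig(seed=42, n_days=1)


@pytest.fixture
def sim_tables(floorplan, schedule, quiet_config):
    return generate_household(floorplan, schedule, quiet_config)


@pytest.fixture
def default_config():
    return ClassifierConfig()


def make_record(
    count,
    hour=12,
    minute=0,
    steps=None,
    house_id="H001",
    day=1,
):
    ts = pd.Timestamp(2024, 1, day, hour, minute)
    return IntervalRecord(house_id, ts, None, count, steps)


def make_labeled_day(label_counts, house_id="H001", day=1):
    """Sequential labeled intervals for one day from {Label: count}."""
    out = []
    i = 0
    for label, n in label_counts.items():
        for _ in range(n):
            ts = pd.Timestamp(2024, 1, day) + pd.Timedelta(minutes=5 * i)
            count = None if label is Label.EXCLUDED else 1
            reason = ExclusionReason.MISSING if label is Label.EXCLUDED else None
            out.append(LabeledInterval(IntervalRecord(house_id, ts, None, count), label, reason))
            i += 1
    return out
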