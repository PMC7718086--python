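"""Rule-based labeling of 5-minute intervals into behavior states.

Within the waking window (default 08:00-22:00): an activation count at or
above the physical-activity threshold is PHYSICAL_ACTIVITY, a lower
non-zero count is SEDENTARY, and zero activations is AWAY.  Within the
sleep window (the waking window's complement): zero activations is SLEEP
and any movement is DISTURBED_SLEEP.  Two data-hygiene filters relabel
intervals as EXCLUDED: step outliers (more than ``outlier_step_threshold``
steps in one interval, e.g. treadmill use) and isolated single-sensor
activations with no steps (noise such as a moving curtain).

The literature this follows states the physical-activity cut two ways
(at least 2 sensors under the activity definition; at least 3 in a
three-way sleep/sedentary/activity split), so the threshold is explicit
configuration: ``pa_min_sensors`` defaults to 2 and ``three_way_mode``
switches to the >= 3 variant with 1-2 sensors counting as sedentary.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass

import pandas as pd
import yaml

from passmon.io import IntervalRecord

INTERVAL_MINUTES = 5


class Label(str, enum.Enum):
    SLEEP = "SLEEP"
    DISTURBED_SLEEP = "DISTURBED_SLEEP"
    SEDENTARY = "SEDENTARY"
    PHYSICAL_ACTIVITY = "PHYSICAL_ACTIVITY"
    AWAY = "AWAY"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, enum.Enum):
    STEP_OUTLIER = "STEP_OUTLIER"
    NOISE = "NOISE"
    MISSING = "MISSING"


#: the five behavior states (EXCLUDED is bookkeeping, not behavior)
BEHAVIOR_LABELS = (
    Label.SLEEP,
    Label.DISTURBED_SLEEP,
    Label.SEDENTARY,
    Label.PHYSICAL_ACTIVITY,
    Label.AWAY,
)


def _parse_time(value) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(value)


@dataclass(frozen=True)
class ClassifierConfig:
    """All rule thresholds and time windows.

    The sleep window is always the complement of
    ``[waking_start, waking_end)``; both windows are half-open on the
    5-minute grid.
    """

    waking_start: dt.time = dt.time(8, 0)
    waking_end: dt.time = dt.time(22, 0)
    pa_min_sensors: int = 2
    sleep_sensor_count: int = 0
    outlier_step_threshold: int = 100
    noise_filter_enabled: bool = True
    three_way_mode: bool = False
    away_min_intervals: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "waking_start", _parse_time(self.waking_start))
        object.__setattr__(self, "waking_end", _parse_time(self.waking_end))
        if self.waking_start >= self.waking_end:
            raise ValueError(
                f"waking_start {self.waking_start} must precede waking_end {self.waking_end}"
            )
        if self.pa_min_sensors < 1:
            raise ValueError("pa_min_sensors must be >= 1")
        if self.outlier_step_threshold <= 0:
            raise ValueError("outlier_step_threshold must be positive")
        if self.away_min_intervals < 1:
            raise ValueError("away_min_intervals must be >= 1")

    @property
    def effective_pa_min(self) -> int:
        """The activity threshold actually applied (3 in three-way mode)."""
        return 3 if self.three_way_mode else self.pa_min_sensors

    def in_waking_window(self, t: dt.time) -> bool:
        return self.waking_start <= t < self.waking_end

    @classmethod
    def from_mapping(cls, data: dict) -> "ClassifierConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown classifier config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "ClassifierConfig":
        with open(path) as fh:
            text = fh.read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: classifier config must be a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return {
            "waking_start": self.waking_start.isoformat(timespec="minutes"),
            "waking_end": self.waking_end.isoformat(timespec="minutes"),
            "pa_min_sensors": self.pa_min_sensors,
            "sleep_sensor_count": self.sleep_sensor_count,
            "outlier_step_threshold": self.outlier_step_threshold,
            "noise_filter_enabled": self.noise_filter_enabled,
            "three_way_mode": self.three_way_mode,
            "away_min_intervals": self.away_min_intervals,
        }


@dataclass(frozen=True)
class LabeledInterval:
    """An interval record plus exactly one label.

    ``exclusion_reason`` is present iff the label is EXCLUDED.
    """

    record: IntervalRecord
    label: Label
    exclusion_reason: ExclusionReason | None = None

    def __post_init__(self) -> None:
        if (self.label is Label.EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason must be present iff label is EXCLUDED")


def classify_interval(record: IntervalRecord, config: ClassifierConfig) -> LabeledInterval:
    """Label one interval from its activation count and clock time alone."""
    count = record.activation_count
    if count is None:
        return LabeledInterval(record, Label.EXCLUDED, ExclusionReason.MISSING)
    t = record.t_start.time()
    if config.in_waking_window(t):
        if count >= config.effective_pa_min:
            return LabeledInterval(record, Label.PHYSICAL_ACTIVITY)
        if count >= 1:
            return LabeledInterval(record, Label.SEDENTARY)
        return LabeledInterval(record, Label.AWAY)
    if count == config.sleep_sensor_count:
        return LabeledInterval(record, Label.SLEEP)
    return LabeledInterval(record, Label.DISTURBED_SLEEP)


def filter_step_outliers(
    labeled: list[LabeledInterval], config: ClassifierConfig
) -> list[LabeledInterval]:
    """Exclude intervals with strictly more than the step threshold.

    The boundary value itself is retained; intervals without step data are
    untouched.  Idempotent.
    """
    out = []
    for li in labeled:
        steps = li.record.steps
        if li.label is not Label.EXCLUDED and steps is not None and steps > config.outlier_step_threshold:
            li = LabeledInterval(li.record, Label.EXCLUDED, ExclusionReason.STEP_OUTLIER)
        out.append(li)
    return out


def filter_noise(labeled: list[LabeledInterval], config: ClassifierConfig) -> list[LabeledInterval]:
    """Exclude isolated spurious single-sensor activations.

    An interval is noise when its activation count is exactly 1, both
    immediate temporal neighbors (same house, +-5 minutes) exist with a
    count of 0, and its steps, if present, are 0.  Neighbor counts are
    evaluated against the original records, so the pass is order-free and
    idempotent.  A disabled filter is the identity.
    """
    if not config.noise_filter_enabled:
        return list(labeled)
    by_key = {(li.record.house_id, li.record.t_start): li.record.activation_count for li in labeled}
    step = pd.Timedelta(minutes=INTERVAL_MINUTES)
    out = []
    for li in labeled:
        r = li.record
        if li.label is Label.EXCLUDED or r.activation_count != 1 or (r.steps or 0) != 0:
            out.append(li)
            continue
        prev = by_key.get((r.house_id, r.t_start - step))
        nxt = by_key.get((r.house_id, r.t_start + step))
        if prev == 0 and nxt == 0:
            li = LabeledInterval(r, Label.EXCLUDED, ExclusionReason.NOISE)
        out.append(li)
    return out


def _merge_short_away_runs(
    labeled: list[LabeledInterval], config: ClassifierConfig
) -> list[LabeledInterval]:
    """Relabel AWAY runs shorter than ``away_min_intervals`` as SEDENTARY."""
    if config.away_min_intervals <= 1:
        return labeled
    out = list(labeled)
    i = 0
    while i < len(out):
        if out[i].label is Label.AWAY:
            j = i
            while (
                j < len(out)
                and out[j].label is Label.AWAY
                and out[j].record.house_id == out[i].record.house_id
            ):
                j += 1
            if j - i < config.away_min_intervals:
                for k in range(i, j):
                    out[k] = LabeledInterval(out[k].record, Label.SEDENTARY)
            i = j
        else:
            i += 1
    return out


def classify_records(
    records: list[IntervalRecord], config: ClassifierConfig
) -> list[LabeledInterval]:
    """Full labeling pipeline over time-sorted records.

    Applies the per-interval rule, the minimum-away-run merge, and then the
    step-outlier and noise filters (filters win over rule labels).
    """
    labeled = [classify_interval(r, config) for r in records]
    labeled = _merge_short_away_runs(labeled, config)
    labeled = filter_step_outliers(labeled, config)
    labeled = filter_noise(labeled, config)
    return labeled


def count_interruptions(labeled_day: list[LabeledInterval]) -> int:
    """Number of maximal runs of consecutive DISTURBED_SLEEP intervals.

    A disturbance spanning several contiguous intervals counts once.
    """
    runs = 0
    prev_disturbed = False
    for li in labeled_day:
        disturbed = li.label is Label.DISTURBED_SLEEP
        if disturbed and not prev_disturbed:
            runs += 1
        prev_disturbed = disturbed
    return runs


def exclusion_tally(labeled: list[LabeledInterval]) -> dict[str, int]:
    """Counts per exclusion reason (data-hygiene reporting)."""
    tally = {reason.value: 0 for reason in ExclusionReason}
    for li in labeled:
        if li.exclusion_reason is not None:
            tally[li.exclusion_reason.value] += 1
    return tally
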