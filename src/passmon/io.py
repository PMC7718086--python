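"""Readers/writers and metadata hygiene for interval, step, and house tables.

CSV dialects (all UTF-8, comma-separated, header row required):

* interval CSV  — ``house_id, timestamp, sensor_1 .. sensor_K`` with 0/1 flags
* steps CSV     — ``house_id, timestamp, steps``
* metadata CSV  — ``house_id, style, floor_area, num_floors, num_occupants``
* labeled CSV   — ``house_id, timestamp, activation_count, steps, label,
  exclusion_reason``

Timestamps are naive local clock time, ISO-8601, aligned to the 5-minute
grid; an interval covers the half-open span ``[t_start, t_start + 5 min)``.
Gaps within a day are materialized as records with a missing activation
count (excluded downstream, never imputed).
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERVAL_MINUTES = 5
INTERVALS_PER_DAY = 288

_SENSOR_COL = re.compile(r"^sensor_(\d+)$")

LABELED_COLUMNS = (
    "house_id",
    "timestamp",
    "activation_count",
    "steps",
    "label",
    "exclusion_reason",
)


class OccupancyClass(str, enum.Enum):
    INDIVIDUAL = "INDIVIDUAL"
    HOUSEHOLD = "HOUSEHOLD"


@dataclass(frozen=True)
class IntervalRecord:
    """One 5-minute interval for one house.

    ``activation_count`` is the number of distinct sensors active in the
    interval; ``None`` marks a gap in the stream.  ``steps`` is absent
    unless a step stream has been joined.
    """

    house_id: str
    t_start: pd.Timestamp
    sensor_flags: tuple[bool, ...] | None
    activation_count: int | None
    steps: int | None = None

    def __post_init__(self) -> None:
        if self.sensor_flags is not None and self.activation_count != sum(self.sensor_flags):
            raise ValueError(
                f"activation_count {self.activation_count} != sum of sensor flags "
                f"for house {self.house_id} at {self.t_start}"
            )
        if self.t_start.minute % INTERVAL_MINUTES or self.t_start.second or self.t_start.microsecond:
            raise ValueError(f"t_start {self.t_start} not aligned to the 5-min grid")
        if self.steps is not None and self.steps < 0:
            raise ValueError("steps must be non-negative")


@dataclass(frozen=True)
class HouseMetadata:
    house_id: str
    style: str
    floor_area: float
    num_floors: int
    num_occupants: int

    def __post_init__(self) -> None:
        if self.num_occupants < 1:
            raise ValueError(
                f"house {self.house_id}: num_occupants must be >= 1, got {self.num_occupants}"
            )
        if self.num_floors < 1:
            raise ValueError(f"house {self.house_id}: num_floors must be >= 1")

    @property
    def occupancy_class(self) -> OccupancyClass:
        """INDIVIDUAL for exactly one occupant, HOUSEHOLD otherwise."""
        return OccupancyClass.INDIVIDUAL if self.num_occupants == 1 else OccupancyClass.HOUSEHOLD


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, format="ISO8601")
    bad = (ts.dt.minute % INTERVAL_MINUTES != 0) | (ts.dt.second != 0) | (ts.dt.microsecond != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: misaligned timestamp {raw.iloc[row]!r} at data row {row + 1} "
            "(must sit on the 5-minute grid)"
        )
    return ts


def read_interval_csv(path, fill_gaps: bool = True) -> list[IntervalRecord]:
    """Read a thermostat-export style interval CSV.

    Records are returned sorted by ``(house_id, t_start)`` with
    ``activation_count`` computed from the per-sensor flags.  Duplicate
    ``(house_id, timestamp)`` rows are rejected.  With ``fill_gaps`` each
    calendar day a house appears on is completed to the full 288-interval
    grid; the filled records carry no flags and no count.
    """
    df = pd.read_csv(path)
    for col in ("house_id", "timestamp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sensor_cols = sorted(
        (c for c in df.columns if _SENSOR_COL.match(c)),
        key=lambda c: int(_SENSOR_COL.match(c).group(1)),
    )
    unknown = [c for c in df.columns if c not in ("house_id", "timestamp") and c not in sensor_cols]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    if not sensor_cols:
        raise ValueError(f"{path}: no sensor_<k> columns found")

    df = df.copy()
    df["house_id"] = df["house_id"].astype(str)
    df["t_start"] = _parse_timestamps(df["timestamp"], path)
    dup = df.duplicated(subset=["house_id", "t_start"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate interval for house {first['house_id']} at "
            f"{first['t_start'].isoformat()}"
        )
    df = df.sort_values(["house_id", "t_start"], kind="mergesort").reset_index(drop=True)
    flags = df[sensor_cols].to_numpy()
    if not np.isin(flags, (0, 1)).all():
        raise ValueError(f"{path}: sensor flags must be 0/1")

    records: list[IntervalRecord] = []
    for i in range(len(df)):
        row_flags = tuple(bool(v) for v in flags[i])
        records.append(
            IntervalRecord(
                house_id=df.at[i, "house_id"],
                t_start=df.at[i, "t_start"],
                sensor_flags=row_flags,
                activation_count=int(sum(row_flags)),
            )
        )
    if fill_gaps:
        records = _fill_gaps(records)
    return records


def _fill_gaps(records: list[IntervalRecord]) -> list[IntervalRecord]:
    by_key = {(r.house_id, r.t_start): r for r in records}
    house_days = sorted({(r.house_id, r.t_start.normalize()) for r in records})
    out: list[IntervalRecord] = []
    for house_id, day in house_days:
        for i in range(INTERVALS_PER_DAY):
            ts = day + pd.Timedelta(minutes=INTERVAL_MINUTES * i)
            rec = by_key.get((house_id, ts))
            if rec is None:
                rec = IntervalRecord(house_id, ts, None, None)
            out.append(rec)
    return out


def read_steps_csv(path) -> pd.DataFrame:
    """Read a steps CSV into a validated frame (house_id, t_start, steps)."""
    df = pd.read_csv(path)
    missing = [c for c in ("house_id", "timestamp", "steps") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["house_id"] = df["house_id"].astype(str)
    df["t_start"] = _parse_timestamps(df["timestamp"], path)
    if (df["steps"] < 0).any():
        raise ValueError(f"{path}: negative step counts")
    df["steps"] = df["steps"].astype(np.int64)
    return df[["house_id", "t_start", "steps"]]


def join_steps(records: list[IntervalRecord], steps: pd.DataFrame) -> list[IntervalRecord]:
    """Left-join a step table onto interval records on (house_id, t_start).

    Intervals without step data keep ``steps=None``; step rows without a
    matching interval raise a warning with their count.
    """
    lookup = {
        (h, t): int(s)
        for h, t, s in zip(steps["house_id"], steps["t_start"], steps["steps"])
    }
    keys = {(r.house_id, r.t_start) for r in records}
    orphans = sum(1 for k in lookup if k not in keys)
    if orphans:
        warnings.warn(f"{orphans} step rows have no matching interval", stacklevel=2)
    out = []
    for r in records:
        s = lookup.get((r.house_id, r.t_start))
        if s is None:
            out.append(r)
        else:
            out.append(
                IntervalRecord(r.house_id, r.t_start, r.sensor_flags, r.activation_count, s)
            )
    return out


def read_metadata_csv(path) -> tuple[list[HouseMetadata], int]:
    """Read household metadata, dropping rows with any incomplete field.

    Returns ``(records, n_dropped)``.  Raises if no rows survive (the
    pipeline cannot stratify) or if a surviving row is invalid (e.g. zero
    occupants).
    """
    df = pd.read_csv(path)
    required = ["house_id", "style", "floor_area", "num_floors", "num_occupants"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[required].copy()
    df["house_id"] = df["house_id"].astype(str)
    for col in ("floor_area", "num_floors", "num_occupants"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    style = df["style"].astype(str).str.strip().str.lower()
    style = style.replace({"": np.nan, "nan": np.nan})
    df["style"] = style.where(style.isin(("apartment", "townhouse", "detached")), other="other")
    df.loc[style.isna(), "style"] = np.nan
    blank_id = df["house_id"].str.strip().isin(("", "nan"))
    keep = df.notna().all(axis=1) & ~blank_id
    n_dropped = int((~keep).sum())
    df = df[keep]
    if df.empty:
        raise ValueError(f"{path}: no complete metadata rows survive filtering")
    records = [
        HouseMetadata(
            house_id=row.house_id,
            style=row.style,
            floor_area=float(row.floor_area),
            num_floors=int(row.num_floors),
            num_occupants=int(row.num_occupants),
        )
        for row in df.itertuples(index=False)
    ]
    return records, n_dropped


def records_to_frame(records: list[IntervalRecord]) -> pd.DataFrame:
    """Render interval records back into the interval-CSV column layout.

    Requires every record to carry sensor flags of a common length.
    """
    if not records:
        return pd.DataFrame(columns=["house_id", "timestamp"])
    widths = {len(r.sensor_flags) for r in records if r.sensor_flags is not None}
    if len(widths) != 1 or any(r.sensor_flags is None for r in records):
        raise ValueError("records must all carry sensor flags of one common length")
    k = widths.pop()
    data = {
        "house_id": [r.house_id for r in records],
        "timestamp": [r.t_start.isoformat() for r in records],
    }
    for j in range(k):
        data[f"sensor_{j + 1}"] = [int(r.sensor_flags[j]) for r in records]
    return pd.DataFrame(data)


def write_labeled_csv(labeled, path) -> None:
    """Write classified intervals to the labeled-CSV dialect."""
    rows = []
    for li in labeled:
        r = li.record
        rows.append(
            {
                "house_id": r.house_id,
                "timestamp": r.t_start.isoformat(),
                "activation_count": "" if r.activation_count is None else r.activation_count,
                "steps": "" if r.steps is None else r.steps,
                "label": li.label.value,
                "exclusion_reason": "" if li.exclusion_reason is None else li.exclusion_reason.value,
            }
        )
    pd.DataFrame(rows, columns=list(LABELED_COLUMNS)).to_csv(path, index=False)


def read_labeled_csv(path):
    """Read a labeled CSV back into LabeledInterval objects."""
    from passmon.classify import ExclusionReason, Label, LabeledInterval

    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in LABELED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["house_id"] = df["house_id"].astype(str)
    df["t_start"] = _parse_timestamps(df["timestamp"], path)
    out = []
    for row in df.itertuples(index=False):
        count = None if row.activation_count == "" else int(float(row.activation_count))
        steps = None if row.steps == "" else int(float(row.steps))
        rec = IntervalRecord(row.house_id, row.t_start, None, count, steps)
        reason = None if row.exclusion_reason == "" else ExclusionReason(row.exclusion_reason)
        out.append(LabeledInterval(rec, Label(row.label), reason))
    return out
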