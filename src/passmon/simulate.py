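"""Agent-based household simulator with ground-truth interval labels.

Generates interval-level sensor activations, indoor step counts, and the
true behavior state of every 5-minute interval for a single-occupant
household, emulating a thermostat-style remote-sensor export plus an
aligned pedometer stream.  All randomness flows through one seeded
generator, so identical inputs reproduce byte-identical CSV output.
"""

from __future__ import annotations

import datetime as dt
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_MINUTES = 5
INTERVALS_PER_DAY = 288

#: labels used in ground-truth tables; mirrors classify.Label values
TRUTH_LABELS = ("SLEEP", "DISTURBED_SLEEP", "SEDENTARY", "PHYSICAL_ACTIVITY", "AWAY")

#: meters walked per step; chosen so that 100 steps correspond to 156 m
DEFAULT_STRIDE_M = 1.56

DEFAULT_START_DATE = dt.date(2024, 1, 1)

INTERVAL_COLUMNS = ("house_id", "timestamp")  # + sensor_<k>
STEP_COLUMNS = ("house_id", "timestamp", "steps")
TRUTH_COLUMNS = ("house_id", "timestamp", "label")


class ScheduleError(ValueError):
    """Occupant schedule does not tile the day (gap, overlap, or bad bout)."""


class FloorplanError(ValueError):
    """Floorplan violates a structural invariant."""


@dataclass(frozen=True)
class FloorplanGraph:
    """Rooms, their sensors, and which rooms are adjacent.

    Parameters
    ----------
    rooms
        Ordered room identifiers.
    sensors
        Mapping room -> sensor identifiers placed in that room (>= 1 each).
        Sensor identifiers must be globally unique.
    adjacency
        Undirected room pairs; each pair is stored symmetrically.
    room_distance
        Meters walked per traversal between two adjacent rooms.
    """

    rooms: tuple[str, ...]
    sensors: dict[str, tuple[str, ...]]
    adjacency: tuple[tuple[str, str], ...]
    room_distance: float = 10.0

    def __post_init__(self) -> None:
        if len(self.rooms) < 2:
            raise FloorplanError("floorplan needs at least 2 rooms")
        if len(set(self.rooms)) != len(self.rooms):
            raise FloorplanError("duplicate room identifiers")
        if set(self.sensors) != set(self.rooms):
            raise FloorplanError("sensors mapping must cover exactly the rooms")
        all_sensors = [s for room in self.rooms for s in self.sensors[room]]
        if any(len(self.sensors[r]) < 1 for r in self.rooms):
            raise FloorplanError("every room needs at least one sensor")
        if len(set(all_sensors)) != len(all_sensors):
            raise FloorplanError("a sensor may belong to exactly one room")
        if not 5 <= len(all_sensors) <= 30:
            raise FloorplanError(
                f"total sensor count {len(all_sensors)} outside the supported 5..30 range"
            )
        for a, b in self.adjacency:
            if a not in self.sensors or b not in self.sensors:
                raise FloorplanError(f"adjacency references unknown room in ({a}, {b})")
            if a == b:
                raise FloorplanError(f"room {a} cannot be adjacent to itself")
        if self.room_distance <= 0:
            raise FloorplanError("room_distance must be positive")
        # connectivity (adjacency treated as symmetric regardless of pair order)
        seen = {self.rooms[0]}
        queue = deque([self.rooms[0]])
        while queue:
            room = queue.popleft()
            for nxt in self.neighbors(room):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        if seen != set(self.rooms):
            missing = sorted(set(self.rooms) - seen)
            raise FloorplanError(f"floorplan graph is not connected; unreachable: {missing}")

    def neighbors(self, room: str) -> tuple[str, ...]:
        out = []
        for a, b in self.adjacency:
            if a == room:
                out.append(b)
            elif b == room:
                out.append(a)
        return tuple(dict.fromkeys(out))

    @property
    def sensor_ids(self) -> tuple[str, ...]:
        """All sensors in deterministic (room-major) order."""
        return tuple(s for room in self.rooms for s in self.sensors[room])


def _parse_time(value: dt.time | str) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(value)


@dataclass(frozen=True)
class OccupantSchedule:
    """Daily routine of a single occupant.

    The sleep window must wrap midnight (``sleep_start > sleep_end``, e.g.
    22:00 -> 08:00); its complement is the waking window.  Away and activity
    bouts are half-open clock-time spans inside the waking window; activity
    bouts carry a rooms-visited-per-interval rate (>= 2, so that movement
    always reaches a second sensor within the interval).
    """

    sleep_start: dt.time = dt.time(22, 0)
    sleep_end: dt.time = dt.time(8, 0)
    away_bouts: tuple[tuple[dt.time, dt.time], ...] = ()
    activity_bouts: tuple[tuple[dt.time, dt.time, float], ...] = ()
    stride_m: float = DEFAULT_STRIDE_M

    def __post_init__(self) -> None:
        object.__setattr__(self, "sleep_start", _parse_time(self.sleep_start))
        object.__setattr__(self, "sleep_end", _parse_time(self.sleep_end))
        object.__setattr__(
            self,
            "away_bouts",
            tuple((_parse_time(s), _parse_time(e)) for s, e in self.away_bouts),
        )
        object.__setattr__(
            self,
            "activity_bouts",
            tuple((_parse_time(s), _parse_time(e), float(r)) for s, e, r in self.activity_bouts),
        )
        if self.stride_m <= 0:
            raise ScheduleError("stride_m must be positive")
        if self.sleep_start <= self.sleep_end:
            raise ScheduleError(
                "sleep window must wrap midnight (sleep_start > sleep_end); got "
                f"{self.sleep_start}..{self.sleep_end}"
            )
        spans = [(s, e, "away") for s, e in self.away_bouts]
        spans += [(s, e, "activity") for s, e, _ in self.activity_bouts]
        for s, e, kind in spans:
            if s >= e:
                raise ScheduleError(f"{kind} bout {s}-{e} is empty or reversed")
            if s < self.sleep_end or e > self.sleep_start:
                raise ScheduleError(
                    f"{kind} bout {s}-{e} extends outside the waking window "
                    f"{self.sleep_end}-{self.sleep_start}"
                )
        spans.sort(key=lambda x: x[0])
        for (s1, e1, k1), (s2, e2, k2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ScheduleError(
                    f"bouts overlap: {k1} {s1}-{e1} and {k2} {s2}-{e2}"
                )
        for s, e, rate in self.activity_bouts:
            if rate < 2:
                raise ScheduleError(
                    f"activity bout {s}-{e} rate {rate} < 2 rooms/interval; "
                    "movement must reach a second room"
                )

    def state_at(self, t: dt.time) -> tuple[str, float | None]:
        """Generating state at clock time ``t`` (an interval start)."""
        if t >= self.sleep_start or t < self.sleep_end:
            return "SLEEP", None
        for s, e in self.away_bouts:
            if s <= t < e:
                return "AWAY", None
        for s, e, rate in self.activity_bouts:
            if s <= t < e:
                return "PHYSICAL_ACTIVITY", rate
        return "SEDENTARY", None


@dataclass(frozen=True)
class SimConfig:
    """Stochastic knobs for one simulated household.

    noise_rate is the per-interval probability of a spurious, temporally
    isolated single-sensor activation on an otherwise empty interval;
    sleep_interruption_rate is the per-sleep-interval probability of a real
    movement event (which, unlike noise, produces steps).
    """

    seed: int = 0
    n_days: int = 1
    noise_rate: float = 0.0
    sleep_interruption_rate: float = 0.0
    steps_per_transition_mean: float | None = None
    sedentary_fire_rate: float = 1.0
    sedentary_steps_mean: float = 1.5
    interruption_steps_mean: float = 4.0
    start_date: dt.date = DEFAULT_START_DATE

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("noise_rate", "sleep_interruption_rate", "sedentary_fire_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.steps_per_transition_mean is not None and self.steps_per_transition_mean <= 0:
            raise ValueError("steps_per_transition_mean must be positive")


def generate_household(
    floorplan: FloorplanGraph,
    schedule: OccupantSchedule,
    config: SimConfig,
    house_id: str = "H001",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one household.

    Returns ``(intervals, steps, truth)`` dataframes on a shared 5-minute
    grid (288 rows per day).  ``intervals`` has one 0/1 column per sensor;
    ``steps`` holds indoor steps (0 while away); ``truth`` holds the
    generating state of every interval.
    """
    rng = np.random.default_rng(config.seed)
    sensor_ids = floorplan.sensor_ids
    sensor_pos = {sid: i for i, sid in enumerate(sensor_ids)}
    steps_per_transition = (
        config.steps_per_transition_mean
        if config.steps_per_transition_mean is not None
        else floorplan.room_distance / schedule.stride_m
    )
    bed_room = floorplan.rooms[0]
    lounge_room = floorplan.rooms[1 % len(floorplan.rooms)]

    n = config.n_days * INTERVALS_PER_DAY
    timestamps: list[dt.datetime] = []
    active: list[set[str]] = []
    steps: list[int] = []
    labels: list[str] = []

    day0 = dt.datetime.combine(config.start_date, dt.time(0, 0))
    for i in range(n):
        ts = day0 + dt.timedelta(minutes=INTERVAL_MINUTES * i)
        state, rate = schedule.state_at(ts.time())
        fired: set[str] = set()
        n_steps = 0
        if state == "SLEEP":
            if config.sleep_interruption_rate and rng.random() < config.sleep_interruption_rate:
                state = "DISTURBED_SLEEP"
                fired = {floorplan.sensors[bed_room][0]}
                n_steps = 1 + int(rng.poisson(config.interruption_steps_mean))
        elif state == "SEDENTARY":
            if rng.random() < config.sedentary_fire_rate:
                fired = {floorplan.sensors[lounge_room][0]}
                n_steps = int(rng.poisson(config.sedentary_steps_mean))
        elif state == "PHYSICAL_ACTIVITY":
            room = floorplan.rooms[rng.integers(len(floorplan.rooms))]
            visited = [room]
            for _ in range(int(round(rate)) - 1):
                nbrs = floorplan.neighbors(room)
                room = nbrs[rng.integers(len(nbrs))]
                visited.append(room)
            transitions = len(visited) - 1
            for r in set(visited):
                fired.update(floorplan.sensors[r])
            n_steps = int(rng.poisson(transitions * steps_per_transition))
        timestamps.append(ts)
        active.append(fired)
        steps.append(n_steps)
        labels.append(state)

    # spurious single-sensor activations, never on consecutive intervals
    if config.noise_rate > 0:
        for i in range(1, n - 1):
            if (
                not active[i]
                and steps[i] == 0
                and not active[i - 1]
                and not active[i + 1]
                and rng.random() < config.noise_rate
            ):
                active[i] = {sensor_ids[rng.integers(len(sensor_ids))]}

    flags = np.zeros((n, len(sensor_ids)), dtype=np.int64)
    for i, fired in enumerate(active):
        for sid in fired:
            flags[i, sensor_pos[sid]] = 1
    iso = [ts.isoformat() for ts in timestamps]
    intervals = pd.DataFrame({"house_id": house_id, "timestamp": iso})
    for k, _sid in enumerate(sensor_ids):
        intervals[f"sensor_{k + 1}"] = flags[:, k]
    steps_df = pd.DataFrame({"house_id": house_id, "timestamp": iso, "steps": steps})
    truth = pd.DataFrame({"house_id": house_id, "timestamp": iso, "label": labels})
    return intervals, steps_df, truth


def _check_columns(table: pd.DataFrame, required: tuple[str, ...], kind: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns {missing}")


def emit_dyd_csv(table: pd.DataFrame, path) -> None:
    """Write an interval table in the thermostat-export interval dialect."""
    _check_columns(table, INTERVAL_COLUMNS, "interval")
    table.to_csv(path, index=False)


def emit_steps_csv(table: pd.DataFrame, path) -> None:
    _check_columns(table, STEP_COLUMNS, "step")
    table.to_csv(path, index=False)


def emit_truth_csv(table: pd.DataFrame, path) -> None:
    _check_columns(table, TRUTH_COLUMNS, "truth")
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# multi-house scenario helpers

_STYLES = ("apartment", "townhouse", "detached", "other")


def random_household(
    rng: np.random.Generator,
    house_id: str,
    num_occupants: int | None = None,
) -> tuple[FloorplanGraph, OccupantSchedule, dict]:
    """Draw a plausible floorplan, daily schedule, and metadata row.

    The sleep window is fixed at 22:00-08:00 so the default classifier
    windows apply; away and activity bouts are drawn on the 5-minute grid
    without overlaps.
    """
    n_rooms = int(rng.integers(4, 9))
    rooms = tuple(f"room{i + 1}" for i in range(n_rooms))
    sensors = {}
    counter = 0
    for r in rooms:
        k = 1 + (1 if rng.random() < 0.4 else 0)
        sensors[r] = tuple(f"s{counter + j + 1}" for j in range(k))
        counter += k
    if counter < 5:  # pad the last room up to the 5-sensor minimum
        extra = 5 - counter
        sensors[rooms[-1]] = sensors[rooms[-1]] + tuple(
            f"s{counter + j + 1}" for j in range(extra)
        )
    adjacency = [(rooms[i], rooms[i + 1]) for i in range(n_rooms - 1)]
    if n_rooms >= 4 and rng.random() < 0.5:
        adjacency.append((rooms[0], rooms[2]))
    floorplan = FloorplanGraph(
        rooms=rooms,
        sensors=sensors,
        adjacency=tuple(adjacency),
        room_distance=float(rng.uniform(6.0, 14.0)),
    )

    taken: list[tuple[int, int]] = []  # occupied waking slots [start, end)

    def _draw_bout(min_slots: int, max_slots: int) -> tuple[int, int] | None:
        for _ in range(50):
            dur = int(rng.integers(min_slots, max_slots + 1))
            start = int(rng.integers(0, 168 - dur))
            if all(start + dur <= s or start >= e for s, e in taken):
                taken.append((start, start + dur))
                return start, start + dur
        return None

    def _slot_time(slot: int) -> dt.time:
        minutes = 8 * 60 + slot * INTERVAL_MINUTES
        return dt.time(minutes // 60, minutes % 60)

    away = []
    for _ in range(int(rng.integers(1, 3))):
        b = _draw_bout(12, 48)  # 1h..4h
        if b:
            away.append((_slot_time(b[0]), _slot_time(b[1]) if b[1] < 168 else dt.time(22, 0)))
    activity = []
    for _ in range(int(rng.integers(2, 5))):
        b = _draw_bout(6, 18)  # 30..90 min
        if b:
            rate = float(rng.integers(2, 5))
            activity.append((_slot_time(b[0]), _slot_time(b[1]), rate))
    schedule = OccupantSchedule(
        away_bouts=tuple(away),
        activity_bouts=tuple(activity),
    )
    occupants = num_occupants if num_occupants is not None else int(rng.integers(1, 5))
    metadata = {
        "house_id": house_id,
        "style": _STYLES[int(rng.integers(len(_STYLES)))],
        "floor_area": int(n_rooms * rng.integers(150, 350)),
        "num_floors": int(rng.integers(1, 3)),
        "num_occupants": occupants,
    }
    return floorplan, schedule, metadata


def simulate_dataset(
    n_houses: int = 8,
    n_days: int = 7,
    seed: int = 0,
    noise_rate: float = 0.0,
    sleep_interruption_rate: float = 0.0,
    multi_occupant_fraction: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort of households onto one shared table set.

    Houses differ in floorplan and schedule; sensor columns are the union
    across houses (absent sensors read 0).  With
    ``multi_occupant_fraction`` > 0 a matching share of houses get more
    than one declared occupant in the metadata (the simulated movement is
    still a single agent; occupant disambiguation is out of scope).
    """
    root = np.random.default_rng(seed)
    intervals, steps, truth, meta = [], [], [], []
    for h in range(n_houses):
        house_id = f"H{h + 1:03d}"
        multi = root.random() < multi_occupant_fraction
        rng = np.random.default_rng(root.integers(2**63))
        floorplan, schedule, md = random_household(
            rng, house_id, num_occupants=None if multi else 1
        )
        if multi and md["num_occupants"] == 1:
            md["num_occupants"] = 2
        cfg = SimConfig(
            seed=int(rng.integers(2**63)),
            n_days=n_days,
            noise_rate=noise_rate,
            sleep_interruption_rate=sleep_interruption_rate,
        )
        iv, st, tr = generate_household(floorplan, schedule, cfg, house_id=house_id)
        intervals.append(iv)
        steps.append(st)
        truth.append(tr)
        meta.append(md)
    all_iv = pd.concat(intervals, ignore_index=True)
    sensor_cols = [c for c in all_iv.columns if c.startswith("sensor_")]
    all_iv[sensor_cols] = all_iv[sensor_cols].fillna(0).astype(np.int64)
    return {
        "intervals": all_iv,
        "steps": pd.concat(steps, ignore_index=True),
        "truth": pd.concat(truth, ignore_index=True),
        "metadata": pd.DataFrame(meta),
    }


def pilot_dataset(
    seed: int = 0,
    n_houses: int = 8,
    n_days: int = 7,
    noise_rate: float = 0.02,
    sleep_interruption_rate: float = 0.04,
) -> dict[str, pd.DataFrame]:
    """Pilot-shaped cohort: solo occupants wearing a step counter."""
    return simulate_dataset(
        n_houses=n_houses,
        n_days=n_days,
        seed=seed,
        noise_rate=noise_rate,
        sleep_interruption_rate=sleep_interruption_rate,
        multi_occupant_fraction=0.0,
    )
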