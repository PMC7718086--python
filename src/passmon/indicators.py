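"""Daily time-use indicators and stratified summaries.

Each house-day of 288 labeled intervals is reduced to five behavior
indicators (nighttime sleep, disturbed sleep, sedentary time, away period
in hours; in-house physical activity in minutes) plus excluded time and a
count of sleep interruptions.  The components partition the 24-hour day
exactly.  Summaries stratify houses into INDIVIDUAL (one occupant) vs
HOUSEHOLD (more than one) and report deltas against fixed national
reference values for sleep, physical activity, and sedentary time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from passmon.classify import Label, LabeledInterval, count_interruptions
from passmon.io import INTERVALS_PER_DAY, HouseMetadata, OccupancyClass

#: national survey reference values the indicators are compared against
#: (sleep hours/day, in-house physical activity minutes/day, sedentary hours/day)
PASS_REFERENCE = {"sleep_h": 7.2, "pa_min": 24.1, "sedentary_h": 9.6}

INDICATOR_FIELDS = (
    "sleep_h",
    "disturbed_sleep_h",
    "sedentary_h",
    "pa_min",
    "away_h",
    "excluded_h",
    "n_interruptions",
)


@dataclass(frozen=True)
class DailyIndicators:
    """Per-house per-day indicator totals, partitioning 24 hours.

    Interval counts are authoritative; the hour/minute views are derived
    (one interval = 5 minutes).
    """

    house_id: str
    date: object  # datetime.date
    n_sleep: int
    n_disturbed: int
    n_sedentary: int
    n_pa: int
    n_away: int
    n_excluded: int
    n_interruptions: int

    def __post_init__(self) -> None:
        total = self.total_intervals
        if total != INTERVALS_PER_DAY:
            raise ValueError(
                f"house {self.house_id} day {self.date}: {total} intervals, "
                f"expected {INTERVALS_PER_DAY}"
            )

    @property
    def total_intervals(self) -> int:
        return (
            self.n_sleep
            + self.n_disturbed
            + self.n_sedentary
            + self.n_pa
            + self.n_away
            + self.n_excluded
        )

    @property
    def sleep_h(self) -> float:
        return self.n_sleep * 5 / 60

    @property
    def disturbed_sleep_h(self) -> float:
        return self.n_disturbed * 5 / 60

    @property
    def sedentary_h(self) -> float:
        return self.n_sedentary * 5 / 60

    @property
    def pa_min(self) -> float:
        return self.n_pa * 5.0

    @property
    def away_h(self) -> float:
        return self.n_away * 5 / 60

    @property
    def excluded_h(self) -> float:
        return self.n_excluded * 5 / 60

    @property
    def total_hours(self) -> float:
        """Exact total of all components; 24.0 for a complete day."""
        return self.total_intervals * 5 / 60

    def to_dict(self) -> dict:
        return {
            "house_id": self.house_id,
            "date": str(self.date),
            "sleep_h": self.sleep_h,
            "disturbed_sleep_h": self.disturbed_sleep_h,
            "sedentary_h": self.sedentary_h,
            "pa_min": self.pa_min,
            "away_h": self.away_h,
            "excluded_h": self.excluded_h,
            "n_interruptions": self.n_interruptions,
        }


@dataclass(frozen=True)
class IndicatorSummary:
    """Mean indicators for one stratum plus reference deltas."""

    stratum: str  # INDIVIDUAL | HOUSEHOLD | ALL
    n_houses: int
    n_days: int  # house-days
    means: dict
    pass_reference: dict
    pass_delta: dict
    scheme: str  # house_day | per_house

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n_houses": self.n_houses,
            "n_days": self.n_days,
            "means": self.means,
            "pass_reference": self.pass_reference,
            "pass_delta": self.pass_delta,
            "scheme": self.scheme,
        }


_LABEL_SLOT = {
    Label.SLEEP: "n_sleep",
    Label.DISTURBED_SLEEP: "n_disturbed",
    Label.SEDENTARY: "n_sedentary",
    Label.PHYSICAL_ACTIVITY: "n_pa",
    Label.AWAY: "n_away",
    Label.EXCLUDED: "n_excluded",
}


def compute_daily_indicators(labeled_day: list[LabeledInterval]) -> DailyIndicators:
    """Reduce one complete house-day (288 labeled intervals) to indicators."""
    if not labeled_day:
        raise ValueError("empty house-day")
    house_id = labeled_day[0].record.house_id
    date = labeled_day[0].record.t_start.date()
    for li in labeled_day:
        if li.record.house_id != house_id or li.record.t_start.date() != date:
            raise ValueError(
                f"labeled day mixes houses/dates (expected {house_id} {date}, got "
                f"{li.record.house_id} {li.record.t_start.date()})"
            )
    if len(labeled_day) != INTERVALS_PER_DAY:
        raise ValueError(
            f"house {house_id} day {date}: {len(labeled_day)} intervals, "
            f"expected {INTERVALS_PER_DAY}"
        )
    counts = {slot: 0 for slot in _LABEL_SLOT.values()}
    for li in labeled_day:
        counts[_LABEL_SLOT[li.label]] += 1
    ordered = sorted(labeled_day, key=lambda li: li.record.t_start)
    return DailyIndicators(
        house_id=house_id,
        date=date,
        n_interruptions=count_interruptions(ordered),
        **counts,
    )


def daily_indicators(labeled: list[LabeledInterval]) -> list[DailyIndicators]:
    """Group labeled intervals by (house, calendar day) and reduce each."""
    groups: dict[tuple, list[LabeledInterval]] = {}
    for li in labeled:
        groups.setdefault((li.record.house_id, li.record.t_start.date()), []).append(li)
    return [compute_daily_indicators(groups[k]) for k in sorted(groups)]


def indicators_frame(days: list[DailyIndicators]) -> pd.DataFrame:
    return pd.DataFrame([d.to_dict() for d in days])


def _mean_block(rows: pd.DataFrame, scheme: str) -> dict:
    if scheme == "per_house":
        per_house = rows.groupby("house_id")[list(INDICATOR_FIELDS)].mean()
        means = per_house.mean()
    else:
        means = rows[list(INDICATOR_FIELDS)].mean()
    return {k: float(means[k]) for k in INDICATOR_FIELDS}


def summarize(
    days: list[DailyIndicators],
    metadata: list[HouseMetadata],
    scheme: str = "house_day",
) -> dict[str, IndicatorSummary]:
    """Stratified means over house-days (or per-house means, per ``scheme``).

    Houses absent from the metadata are excluded with a warning; ALL covers
    exactly the union of the two strata.
    """
    if scheme not in ("house_day", "per_house"):
        raise ValueError(f"unknown averaging scheme {scheme!r}")
    by_house = {m.house_id: m for m in metadata}
    rows = indicators_frame(days)
    if rows.empty:
        raise ValueError("no house-days to summarize")
    known = rows["house_id"].isin(by_house)
    n_missing_houses = rows.loc[~known, "house_id"].nunique()
    if n_missing_houses:
        warnings.warn(
            f"{n_missing_houses} houses lack metadata and are excluded from summaries",
            stacklevel=2,
        )
    rows = rows[known].copy()
    if rows.empty:
        raise ValueError("no house-days with metadata to summarize")
    rows["stratum"] = rows["house_id"].map(lambda h: by_house[h].occupancy_class.value)

    out: dict[str, IndicatorSummary] = {}
    blocks = {"ALL": rows}
    for cls in (OccupancyClass.INDIVIDUAL, OccupancyClass.HOUSEHOLD):
        blocks[cls.value] = rows[rows["stratum"] == cls.value]
    for stratum, block in blocks.items():
        if block.empty:
            continue
        means = _mean_block(block, scheme)
        delta = {k: means[k] - ref for k, ref in PASS_REFERENCE.items()}
        out[stratum] = IndicatorSummary(
            stratum=stratum,
            n_houses=int(block["house_id"].nunique()),
            n_days=int(len(block)),
            means=means,
            pass_reference=dict(PASS_REFERENCE),
            pass_delta=delta,
            scheme=scheme,
        )
    return out


_REPORT_ROWS = (
    ("Nighttime sleep, hours", "sleep_h", "sleep_h"),
    ("Disturbed sleep, hours", "disturbed_sleep_h", None),
    ("Physical activity in the house, minutes per day", "pa_min", "pa_min"),
    ("Sedentary time, hours", "sedentary_h", "sedentary_h"),
    ("Away period, hours", "away_h", None),
    ("Excluded time, hours", "excluded_h", None),
    ("Sleep interruptions, count per night", "n_interruptions", None),
)


def format_report(summaries: dict[str, IndicatorSummary]) -> str:
    """Plain-text indicator table with strata columns and reference column."""
    strata = [s for s in ("INDIVIDUAL", "HOUSEHOLD", "ALL") if s in summaries]
    header = ["Name of indicator"] + [
        f"{s} (n={summaries[s].n_houses})" for s in strata
    ] + ["Reference"]
    lines = []
    widths = [48] + [max(14, len(h) + 2) for h in header[1:]]
    lines.append("".join(h.ljust(w) for h, w in zip(header, widths)))
    lines.append("-" * sum(widths))
    for name, key, ref_key in _REPORT_ROWS:
        cells = [name.ljust(widths[0])]
        for s, w in zip(strata, widths[1:]):
            cells.append(f"{summaries[s].means[key]:.2f}".ljust(w))
        ref = f"{PASS_REFERENCE[ref_key]:.1f}" if ref_key else "N/A"
        cells.append(ref)
        lines.append("".join(cells))
    return "\n".join(lines) + "\n"
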