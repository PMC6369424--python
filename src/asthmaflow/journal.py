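"""Patient-day self-report records and rolling-window aggregation.

Journal entries are single self-reports (a patient may enter several per
day).  The zone-of-control engine consumes a :class:`WindowAggregate` built
over the trailing window (default 7 days, matching per-week guideline control
criteria); the good-day analytics consume :func:`classify_day`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

from .profiles import DEFAULT_TZ

__all__ = ["JournalEntry", "WindowAggregate", "DayClass", "aggregate_window", "classify_day"]


@dataclass(frozen=True)
class JournalEntry:
    """One self-report: symptom flags, reliever use, triggers, optional PEF."""

    patient_id: str
    timestamp: datetime  # timezone-aware UTC
    daytime_symptoms: bool = False
    night_waking: bool = False
    activity_limitation: bool = False
    severe_flag: bool = False
    reliever_doses: int = 0
    triggers: tuple[str, ...] = ()
    pef: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reliever_doses < 0:
            raise ValueError("reliever_doses must be >= 0")
        if self.pef is not None and self.pef <= 0:
            raise ValueError("pef must be positive when present")
        if self.timestamp.tzinfo is None:
            raise ValueError("journal timestamps must be timezone-aware")


@dataclass(frozen=True)
class WindowAggregate:
    """Counts over a trailing window, the input to symptom classification.

    Day-level counts (``symptom_days``, ``night_wakings``,
    ``activity_limit_days``) count *distinct local calendar days* with at
    least one flagged entry, so several entries on one day are not double
    counted.  ``reliever_doses_total`` sums doses across all entries.
    """

    n_entries: int = 0
    symptom_days: int = 0
    night_wakings: int = 0
    activity_limit_days: int = 0
    reliever_doses_total: int = 0
    severe_any: bool = False
    latest_pef: Optional[float] = None


class DayClass(str, Enum):
    GOOD_DAY = "good_day"
    EPISODE_DAY = "episode_day"


def aggregate_window(
    entries: Sequence[JournalEntry],
    as_of: datetime,
    window_days: int = 7,
    tz: str = DEFAULT_TZ,
) -> WindowAggregate:
    """Aggregate entries with ``as_of - window_days < timestamp <= as_of``.

    Insensitive to entry ordering; an empty window yields all-zero counts.
    ``latest_pef`` is the PEF of the most recent in-window entry that has one.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    start = as_of - timedelta(days=window_days)
    tzinfo = ZoneInfo(tz)

    in_window = [e for e in entries if start < e.timestamp <= as_of]
    symptom_days: set[date] = set()
    waking_days: set[date] = set()
    activity_days: set[date] = set()
    reliever_total = 0
    severe_any = False
    latest_pef: Optional[float] = None
    latest_pef_ts: Optional[datetime] = None
    for e in in_window:
        local_day = e.timestamp.astimezone(tzinfo).date()
        if e.daytime_symptoms:
            symptom_days.add(local_day)
        if e.night_waking:
            waking_days.add(local_day)
        if e.activity_limitation:
            activity_days.add(local_day)
        reliever_total += e.reliever_doses
        severe_any = severe_any or e.severe_flag
        if e.pef is not None and (latest_pef_ts is None or e.timestamp > latest_pef_ts):
            latest_pef = e.pef
            latest_pef_ts = e.timestamp
    return WindowAggregate(
        n_entries=len(in_window),
        symptom_days=len(symptom_days),
        night_wakings=len(waking_days),
        activity_limit_days=len(activity_days),
        reliever_doses_total=reliever_total,
        severe_any=severe_any,
        latest_pef=latest_pef,
    )


def classify_day(entry: JournalEntry) -> DayClass:
    """A good day has no symptom flags of any kind and no reliever use.

    Reliever use implies symptoms, so a reliever-only day counts as an
    episode day.
    """
    if (
        not entry.daytime_symptoms
        and not entry.night_waking
        and not entry.activity_limitation
        and not entry.severe_flag
        and entry.reliever_doses == 0
    ):
        return DayClass.GOOD_DAY
    return DayClass.EPISODE_DAY
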