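"""Utilization and questionnaire analytics over platform event logs.

All usage metrics are computed directly from the append-only event log:

* per-patient-per-week (pppw) event rates, normalized by cohort size and the
  full observation period (default 52 weeks);
* weekly-active fractions and the attrition curve, on enrollment-relative
  patient clocks (week 1 starts at each patient's enrollment);
* login counts by local hour of day (optionally split by enrollment-relative
  month) — the view in which an evening reminder-response spike and a
  morning usage peak appear;
* zone-of-control outcome distributions, trigger frequencies, monthly
  good-day vs episode-day counts, and per-patient weeks-with-login;
* Wilcoxon rank-sum subgroup comparisons, System Usability Scale (SUS)
  scoring, and 5-point Likert item summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta
from scipy import stats

from .event_log import EventLog, EventType, filter_events, journal_entries_from_log
from .journal import DayClass, JournalEntry, classify_day
from .profiles import DEFAULT_TZ, PatientProfile, Zone

__all__ = [
    "UtilizationSummary",
    "pppw_rate",
    "enrollment_week",
    "weekly_active_fraction",
    "attrition_curve",
    "hour_histogram",
    "zone_distribution",
    "trigger_frequency",
    "good_day_monthly",
    "weeks_with_login",
    "rank_sum_compare",
    "sus_score",
    "likert_summary",
    "summarize_utilization",
]


# ---------------------------------------------------------------------------
# Rates and activity
# ---------------------------------------------------------------------------

def pppw_rate(total_events: int, n_patients: int, n_weeks: int) -> float:
    """Events per patient per week: total / (patients x weeks)."""
    if n_patients < 1 or n_weeks < 1:
        raise ValueError("n_patients and n_weeks must be >= 1")
    return total_events / (n_patients * n_weeks)


def _default_enrollments(log: EventLog) -> dict[str, datetime]:
    """Fall back to each patient's first logged event as enrollment."""
    first: dict[str, datetime] = {}
    for r in log.records:
        if r.patient_id not in first or r.timestamp < first[r.patient_id]:
            first[r.patient_id] = r.timestamp
    return first


def enrollment_week(
    ts: datetime, enrollment: datetime, tz: str = DEFAULT_TZ
) -> int:
    """1-based enrollment-relative week index of a timestamp (local days)."""
    tzinfo = ZoneInfo(tz)
    days = (ts.astimezone(tzinfo).date() - enrollment.astimezone(tzinfo).date()).days
    return days // 7 + 1


def _enrollment_month(ts: datetime, enrollment: datetime, tz: str = DEFAULT_TZ) -> int:
    """1-based enrollment-relative calendar month index."""
    tzinfo = ZoneInfo(tz)
    t, e = ts.astimezone(tzinfo), enrollment.astimezone(tzinfo)
    months = (t.year - e.year) * 12 + (t.month - e.month)
    if t.day < e.day:
        months -= 1
    return months + 1


def weekly_active_fraction(
    log: EventLog,
    cohort_size: int,
    week: int,
    enrollments: Optional[Mapping[str, datetime]] = None,
    tz: str = DEFAULT_TZ,
) -> float:
    """Fraction of the cohort with >=1 login in enrollment-relative ``week``."""
    if not 1 <= week <= 52:
        raise ValueError("week must be in [1, 52]")
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if enrollments is None:
        enrollments = _default_enrollments(log)
    active = {
        r.patient_id
        for r in filter_events(log, EventType.LOGIN)
        if r.patient_id in enrollments
        and enrollment_week(r.timestamp, enrollments[r.patient_id], tz) == week
    }
    return len(active) / cohort_size


def attrition_curve(
    log: EventLog,
    cohort_size: int,
    enrollments: Optional[Mapping[str, datetime]] = None,
    tz: str = DEFAULT_TZ,
    n_weeks: int = 52,
) -> np.ndarray:
    """Weekly-active fractions for weeks 1..n_weeks (the usage-decay curve)."""
    if enrollments is None:
        enrollments = _default_enrollments(log)
    counts = np.zeros(n_weeks, dtype=float)
    seen: list[set[str]] = [set() for _ in range(n_weeks)]
    for r in filter_events(log, EventType.LOGIN):
        if r.patient_id not in enrollments:
            continue
        w = enrollment_week(r.timestamp, enrollments[r.patient_id], tz)
        if 1 <= w <= n_weeks:
            seen[w - 1].add(r.patient_id)
    counts[:] = [len(s) for s in seen]
    return counts / cohort_size


def hour_histogram(
    log: EventLog,
    by_month: bool = False,
    enrollments: Optional[Mapping[str, datetime]] = None,
    tz: str = DEFAULT_TZ,
    n_months: int = 12,
) -> np.ndarray:
    """Login counts by local hour 0-23; optionally a (24, n_months) matrix
    split by enrollment-relative month.  The histogram conserves the login
    total (out-of-range months are clipped into the nearest bin)."""
    tzinfo = ZoneInfo(tz)
    if by_month and enrollments is None:
        enrollments = _default_enrollments(log)
    shape = (24, n_months) if by_month else (24,)
    hist = np.zeros(shape, dtype=int)
    for r in filter_events(log, EventType.LOGIN):
        hour = r.timestamp.astimezone(tzinfo).hour
        if by_month:
            m = _enrollment_month(r.timestamp, enrollments[r.patient_id], tz)
            hist[hour, min(max(m, 1), n_months) - 1] += 1
        else:
            hist[hour] += 1
    return hist


# ---------------------------------------------------------------------------
# Outcome distributions
# ---------------------------------------------------------------------------

def zone_distribution(log: EventLog) -> dict[Zone, tuple[int, float]]:
    """Zone-calculation outcomes as (count, fraction); fractions sum to 1."""
    calcs = filter_events(log, EventType.ZONE_CALC)
    if len(calcs) == 0:
        raise ValueError("no zone_calc events in log")
    counts = Counter(Zone(r.payload["zone"]) for r in calcs)
    total = sum(counts.values())
    return {z: (c, c / total) for z, c in counts.items()}


def trigger_frequency(entries: Sequence[JournalEntry]) -> dict[str, int]:
    """Trigger mention counts, sorted descending (ties alphabetical)."""
    counts = Counter(t for e in entries for t in e.triggers)
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def good_day_monthly(
    entries: Sequence[JournalEntry],
    enrollments: Optional[Mapping[str, datetime]] = None,
    tz: str = DEFAULT_TZ,
    n_months: int = 12,
) -> pd.DataFrame:
    """Per enrollment-relative month: good-day and episode-day counts.

    A patient-day is good only if every entry on that local day is free of
    symptoms and reliever use.  Months with no journaled days are omitted.
    Columns: good, episode, pct_good, pct_episode; index: month 1..n_months.
    """
    if enrollments is None:
        first: dict[str, datetime] = {}
        for e in entries:
            if e.patient_id not in first or e.timestamp < first[e.patient_id]:
                first[e.patient_id] = e.timestamp
        enrollments = first
    tzinfo = ZoneInfo(tz)
    day_good: dict[tuple[str, object], bool] = {}
    day_month: dict[tuple[str, object], int] = {}
    for e in entries:
        key = (e.patient_id, e.timestamp.astimezone(tzinfo).date())
        good = classify_day(e) == DayClass.GOOD_DAY
        day_good[key] = day_good.get(key, True) and good
        day_month[key] = _enrollment_month(e.timestamp, enrollments[e.patient_id], tz)
    rows: dict[int, list[int]] = {}
    for key, good in day_good.items():
        m = day_month[key]
        if not 1 <= m <= n_months:
            continue
        rows.setdefault(m, [0, 0])[0 if good else 1] += 1
    data = []
    for m in sorted(rows):
        g, ep = rows[m]
        total = g + ep
        data.append(
            {
                "month": m,
                "good": g,
                "episode": ep,
                "pct_good": 100 * g / total,
                "pct_episode": 100 * ep / total,
            }
        )
    return pd.DataFrame(data).set_index("month") if data else pd.DataFrame(
        columns=["good", "episode", "pct_good", "pct_episode"]
    )


def weeks_with_login(
    log: EventLog,
    patient_id: str,
    enrollment: Optional[datetime] = None,
    tz: str = DEFAULT_TZ,
    n_weeks: int = 52,
) -> int:
    """Number of distinct enrollment-relative weeks (1..52) with >=1 login."""
    logins = filter_events(log, EventType.LOGIN, patient_id=patient_id)
    if enrollment is None:
        enrollment = _default_enrollments(log).get(patient_id)
        if enrollment is None:
            return 0
    weeks = {
        enrollment_week(r.timestamp, enrollment, tz)
        for r in logins
    }
    return len({w for w in weeks if 1 <= w <= n_weeks})


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def rank_sum_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two independent groups.

    Returns the rank-sum statistic W of ``group_a`` and the two-sided p.
    The exact null distribution is used when the smaller group has at most
    10 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(a.size, b.size) <= 10 and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    # Convert the Mann-Whitney U of group_a to its rank-sum statistic.
    w = float(res.statistic) + a.size * (a.size + 1) / 2
    return w, float(res.pvalue)


def sus_score(responses: Sequence[int]) -> float:
    """System Usability Scale score (0-100) from the 10 ordered items.

    Odd items contribute (response - 1), even items (5 - response); the sum
    is scaled by 2.5.
    """
    if len(responses) != 10:
        raise ValueError("SUS requires exactly 10 item responses")
    if any(not 1 <= r <= 5 for r in responses):
        raise ValueError("SUS responses must be integers in [1, 5]")
    total = sum(
        (r - 1) if i % 2 == 0 else (5 - r) for i, r in enumerate(responses)
    )
    return 2.5 * total


def likert_summary(table: pd.DataFrame, item_id: str) -> dict[str, float]:
    """Bucketed percentages for one 5-point Likert item.

    ``table`` has columns respondent_id, item_id, response (1-5).  Responses
    1-2 bucket to disagree, 3 to neutral, 4-5 to agree; percentages are over
    non-missing responses, rounded to 1 decimal.
    """
    rows = table[table["item_id"] == item_id]
    responses = rows["response"].dropna().astype(int)
    if len(responses) == 0:
        raise ValueError(f"no responses for item {item_id!r}")
    if not responses.between(1, 5).all():
        raise ValueError("Likert responses must be in [1, 5]")
    n = len(responses)
    return {
        "n": n,
        "pct_disagree": round(100 * (responses <= 2).sum() / n, 1),
        "pct_neutral": round(100 * (responses == 3).sum() / n, 1),
        "pct_agree": round(100 * (responses >= 4).sum() / n, 1),
    }


# ---------------------------------------------------------------------------
# Cohort-level summary bundle
# ---------------------------------------------------------------------------

@dataclass
class UtilizationSummary:
    """Cohort-level metric bundle mirroring a platform utilization report."""

    n_patients: int
    n_weeks: int
    totals: dict[str, int]
    pppw: dict[str, float]
    weekly_active: np.ndarray
    hour_histogram: np.ndarray
    zone_proportions: dict[str, tuple[int, float]]
    weeks_with_login: dict[str, int]
    good_day_monthly: pd.DataFrame

    def to_obj(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_weeks": self.n_weeks,
            "totals": self.totals,
            "pppw": {k: round(v, 2) for k, v in self.pppw.items()},
            "weekly_active": [round(float(x), 4) for x in self.weekly_active],
            "hour_histogram": [int(x) for x in np.asarray(self.hour_histogram)],
            "zone_proportions": {
                z: {"count": c, "pct": round(100 * f, 2)}
                for z, (c, f) in self.zone_proportions.items()
            },
            "weeks_with_login": self.weeks_with_login,
            "good_day_monthly": self.good_day_monthly.reset_index().to_dict(
                orient="records"
            ),
        }


def summarize_utilization(
    log: EventLog,
    profiles: Sequence[PatientProfile],
    n_weeks: int = 52,
    tz: str = DEFAULT_TZ,
) -> UtilizationSummary:
    """Compute the full cohort utilization report from a log and cohort."""
    enrollments = {p.patient_id: p.enrollment for p in profiles}
    n_patients = len(profiles)
    totals = Counter(r.event_type.value for r in log.records)
    pppw = {
        etype: pppw_rate(totals.get(etype, 0), n_patients, n_weeks)
        for etype in (e.value for e in EventType)
    }
    try:
        zones = {z.value: v for z, v in zone_distribution(log).items()}
    except ValueError:
        zones = {}
    entries = journal_entries_from_log(log)
    return UtilizationSummary(
        n_patients=n_patients,
        n_weeks=n_weeks,
        totals=dict(totals),
        pppw=pppw,
        weekly_active=attrition_curve(log, n_patients, enrollments, tz, n_weeks),
        hour_histogram=hour_histogram(log, tz=tz),
        zone_proportions=zones,
        weeks_with_login={
            p.patient_id: weeks_with_login(log, p.patient_id, p.enrollment, tz, n_weeks)
            for p in profiles
        },
        good_day_monthly=good_day_monthly(entries, enrollments, tz),
    )
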