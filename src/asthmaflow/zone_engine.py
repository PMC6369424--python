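"""Zone-of-control decision engine.

Maps a patient's recent journal window (symptoms, reliever use, optional
peak flow) to a traffic-light zone of control — green (in control), yellow
(uncontrolled), red (dangerously uncontrolled) — or to an explicit
*insufficient* outcome when there is not enough information to classify.

The symptom criteria follow weekly asthma-control guideline conventions:
green requires daytime symptoms on fewer than 4 days/week, no night waking,
at most 3 reliever doses/week, and no activity limitation; danger-level
symptoms force red.  The symptom and peak-flow components are combined
safety-conservatively (worst-of).  After a patient executes their action
plan the assessment window resets: only journal entries strictly after the
reset contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Optional, Sequence

from .journal import JournalEntry, WindowAggregate, aggregate_window
from .profiles import (
    ActionPlan,
    DEFAULT_GREEN_FRACTION,
    DEFAULT_RED_FRACTION,
    PatientProfile,
    ThresholdError,
    ZoneInstruction,
    ZoneThresholds,
    Zone,
    resolve_pef_thresholds,
)

__all__ = [
    "SymptomCriteria",
    "Basis",
    "ZoneResult",
    "classify_pef",
    "classify_symptoms",
    "assess_zone",
    "apply_reset",
]

_SEVERITY = {Zone.GREEN: 0, Zone.YELLOW: 1, Zone.RED: 2}


@dataclass(frozen=True)
class SymptomCriteria:
    """Weekly symptom thresholds for the green zone (inclusive maxima)."""

    max_symptom_days_per_week: int = 3
    max_night_wakings: int = 0
    max_reliever_doses_per_week: int = 3
    allow_activity_limitation: bool = False

    def __post_init__(self) -> None:
        if min(
            self.max_symptom_days_per_week,
            self.max_night_wakings,
            self.max_reliever_doses_per_week,
        ) < 0:
            raise ValueError("criteria counts must be >= 0")


class Basis(str, Enum):
    """Which information components supported an assessment."""

    SYMPTOMS_ONLY = "symptoms_only"
    PEF_ONLY = "pef_only"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class ZoneResult:
    zone: Zone
    basis: Basis
    as_of: datetime
    contributing_window: tuple[datetime, datetime]
    instruction: Optional[ZoneInstruction] = None


def classify_pef(pef: float, thresholds: ZoneThresholds) -> Zone:
    """Band a peak-flow reading; zone lower bounds are inclusive."""
    if pef <= 0:
        raise ValueError(f"invalid peak-flow measurement: {pef}")
    if not thresholds.is_valid():
        raise ValueError(
            "thresholds must satisfy green_lower > yellow_lower > 0"
        )
    if pef >= thresholds.green_lower:
        return Zone.GREEN
    if pef < thresholds.yellow_lower:
        return Zone.RED
    return Zone.YELLOW


def classify_symptoms(agg: WindowAggregate, criteria: SymptomCriteria = SymptomCriteria()) -> Zone:
    """Classify a non-empty symptom aggregate.

    Danger-level symptoms dominate (red); green requires every criterion to
    be met; anything in between is yellow.
    """
    if agg.n_entries <= 0:
        raise ValueError("classify_symptoms requires a non-empty aggregate")
    if agg.severe_any:
        return Zone.RED
    if (
        agg.symptom_days <= criteria.max_symptom_days_per_week
        and agg.night_wakings <= criteria.max_night_wakings
        and agg.reliever_doses_total <= criteria.max_reliever_doses_per_week
        and (agg.activity_limit_days == 0 or criteria.allow_activity_limitation)
    ):
        return Zone.GREEN
    return Zone.YELLOW


def assess_zone(
    profile: PatientProfile,
    plan: ActionPlan,
    entries: Sequence[JournalEntry],
    as_of: datetime,
    criteria: SymptomCriteria = SymptomCriteria(),
    window_days: int = 7,
    green_frac: float = DEFAULT_GREEN_FRACTION,
    red_frac: float = DEFAULT_RED_FRACTION,
    pef_readings: Sequence[tuple[datetime, float]] = (),
) -> ZoneResult:
    """Assess the current zone of control from the trailing journal window.

    The symptom component uses all in-window entries; the peak-flow
    component uses the most recent in-window PEF value — whether embedded
    in a journal entry or logged as a standalone measurement in
    ``pef_readings`` — banded against the profile's resolved thresholds.
    Available components combine worst-of (red > yellow > green).  The
    result is *insufficient* when there is no in-window information at all,
    or when the plan requires peak flow but thresholds cannot be resolved.
    For classifiable outcomes the result carries the plan's instruction
    record for the returned zone.  A PEF older than the window never
    contributes.
    """
    window = (as_of - timedelta(days=window_days), as_of)
    agg = aggregate_window(entries, as_of, window_days=window_days, tz=profile.tz)

    pef_candidates = [
        (e.timestamp, e.pef)
        for e in entries
        if e.pef is not None and window[0] < e.timestamp <= as_of
    ] + [(t, v) for t, v in pef_readings if window[0] < t <= as_of]
    latest_pef = max(pef_candidates, key=lambda tv: tv[0])[1] if pef_candidates else None

    thresholds: Optional[ZoneThresholds] = None
    thresholds_err = False
    try:
        thresholds = resolve_pef_thresholds(profile, green_frac, red_frac)
    except ThresholdError:
        thresholds_err = True

    if plan.requires_pef and thresholds_err:
        return ZoneResult(Zone.INSUFFICIENT, Basis.NONE, as_of, window)

    symptom_zone = classify_symptoms(agg, criteria) if agg.n_entries > 0 else None
    pef_zone = (
        classify_pef(latest_pef, thresholds)
        if latest_pef is not None and thresholds is not None
        else None
    )

    if symptom_zone is None and pef_zone is None:
        return ZoneResult(Zone.INSUFFICIENT, Basis.NONE, as_of, window)
    if symptom_zone is not None and pef_zone is not None:
        basis = Basis.BOTH
        zone = max(symptom_zone, pef_zone, key=_SEVERITY.__getitem__)
    elif symptom_zone is not None:
        basis, zone = Basis.SYMPTOMS_ONLY, symptom_zone
    else:
        basis, zone = Basis.PEF_ONLY, pef_zone
    return ZoneResult(zone, basis, as_of, window, instruction=plan.instruction_for(zone))


def apply_reset(
    entries: Sequence[JournalEntry],
    reset_events: Sequence[datetime],
    as_of: datetime,
) -> list[JournalEntry]:
    """Drop entries consumed by the most recent executed action plan.

    Returns only entries strictly after the latest reset at or before
    ``as_of`` (the executed plan consumes the entries that triggered it).
    With no applicable reset this is the identity.
    """
    applicable = [t for t in reset_events if t <= as_of]
    if not applicable:
        return list(entries)
    cutoff = max(applicable)
    return [e for e in entries if e.timestamp > cutoff]
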