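"""Provider-authored patient configuration: the "asthma app prescription".

A clinician configures, per patient, the medication list, an individualized
per-zone action plan, and (when peak flow is part of the plan) either absolute
peak-expiratory-flow (PEF) zone boundaries or a personal best from which the
boundaries are derived.  The platform never invents any of this content; it
only validates and resolves it.

Timestamps are stored as timezone-aware UTC datetimes throughout the package;
each profile carries an IANA timezone (default ``America/Toronto``) used to
interpret clock times such as the reminder hour and to bucket events into
local calendar days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence
from zoneinfo import ZoneInfo

__all__ = [
    "Zone",
    "MedClass",
    "ThresholdSource",
    "AgeGroup",
    "Medication",
    "ZoneThresholds",
    "ZoneInstruction",
    "ActionPlan",
    "PatientProfile",
    "ThresholdError",
    "DEFAULT_GREEN_FRACTION",
    "DEFAULT_RED_FRACTION",
    "resolve_pef_thresholds",
    "validate_profile",
    "validate_cohort",
    "load_cohort",
    "save_cohort",
]

#: Green zone requires PEF at or above this fraction of personal best.
DEFAULT_GREEN_FRACTION = 0.90
#: Red zone is PEF strictly below this fraction of personal best.
DEFAULT_RED_FRACTION = 0.60

DEFAULT_TZ = "America/Toronto"


class Zone(str, Enum):
    """Traffic-light zone of asthma control."""

    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    INSUFFICIENT = "insufficient"


class MedClass(str, Enum):
    CONTROLLER = "controller"
    RELIEVER = "reliever"


class ThresholdSource(str, Enum):
    ABSOLUTE = "absolute"
    FRACTION_OF_PERSONAL_BEST = "fraction_of_personal_best"


class AgeGroup(str, Enum):
    UNDER_50 = "under_50"
    FIFTY_PLUS = "fifty_plus"


class ThresholdError(ValueError):
    """Raised when PEF zone thresholds cannot be resolved for a profile."""


@dataclass(frozen=True)
class Medication:
    """One prescribed medication.

    ``schedule`` is a free-form dose description (e.g. "2 puffs BID"); the
    package never interprets it clinically.
    """

    name: str
    med_class: MedClass
    schedule: str = ""


@dataclass(frozen=True)
class ZoneThresholds:
    """Lower PEF bounds (L/min) of the green and yellow zones.

    A reading at or above ``green_lower`` is green, at or above
    ``yellow_lower`` but below ``green_lower`` is yellow, and below
    ``yellow_lower`` is red.  Bounds are inclusive at the lower edge.
    """

    green_lower: float
    yellow_lower: float
    source: ThresholdSource = ThresholdSource.ABSOLUTE

    def is_valid(self) -> bool:
        return self.green_lower > self.yellow_lower > 0


@dataclass(frozen=True)
class ZoneInstruction:
    """Action-plan content for one zone, authored by the provider."""

    zone: Zone
    instructions: str
    medication_adjustments: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ActionPlan:
    """Provider-authored per-zone action plan.

    Exactly one instruction record per acting zone (green/yellow/red).
    ``requires_pef`` marks plans in which peak flow is an integral component:
    for such plans a control assessment is only meaningful when PEF zone
    thresholds can be resolved.
    """

    instructions: Mapping[Zone, ZoneInstruction]
    requires_pef: bool = False

    def instruction_for(self, zone: Zone) -> ZoneInstruction:
        return self.instructions[zone]

    @staticmethod
    def from_texts(
        green: str = "Continue current medications.",
        yellow: str = "Step up therapy per plan and monitor closely.",
        red: str = "Take reliever, start rescue plan, seek urgent care.",
        requires_pef: bool = False,
    ) -> "ActionPlan":
        return ActionPlan(
            instructions={
                Zone.GREEN: ZoneInstruction(Zone.GREEN, green),
                Zone.YELLOW: ZoneInstruction(Zone.YELLOW, yellow),
                Zone.RED: ZoneInstruction(Zone.RED, red),
            },
            requires_pef=requires_pef,
        )


@dataclass
class PatientProfile:
    """Clinical and account configuration for one enrolled patient."""

    patient_id: str
    enrollment: datetime
    personal_best_pef: Optional[float] = None
    medications: tuple[Medication, ...] = ()
    thresholds: Optional[ZoneThresholds] = None
    action_plan: Optional[ActionPlan] = None
    reminder_time: time = time(19, 0)
    email_enabled: bool = True
    tz: str = DEFAULT_TZ
    age_group: Optional[AgeGroup] = None
    college_educated: Optional[bool] = None
    has_smartphone: Optional[bool] = None
    baseline_act: Optional[int] = None

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.tz)

    def has_controller(self) -> bool:
        return any(m.med_class == MedClass.CONTROLLER for m in self.medications)


def resolve_pef_thresholds(
    profile: PatientProfile,
    green_frac: float = DEFAULT_GREEN_FRACTION,
    red_frac: float = DEFAULT_RED_FRACTION,
) -> ZoneThresholds:
    """Return absolute PEF zone thresholds for a profile.

    Provider-entered absolute thresholds pass through unchanged.  Otherwise
    the thresholds are derived from the personal best: the green zone floor
    is ``green_frac`` x personal best and the yellow zone floor (below which
    readings are red) is ``red_frac`` x personal best.

    Raises
    ------
    ThresholdError
        If the profile has neither thresholds nor a personal best.
    ValueError
        If the fractions do not satisfy ``0 < red_frac < green_frac <= 1``.
    """
    if profile.thresholds is not None:
        return profile.thresholds
    if not 0 < red_frac < green_frac <= 1:
        raise ValueError(
            f"fractions must satisfy 0 < red_frac < green_frac <= 1; "
            f"got green_frac={green_frac}, red_frac={red_frac}"
        )
    if profile.personal_best_pef is None:
        raise ThresholdError(
            f"thresholds unresolvable for patient {profile.patient_id!r}: "
            "no absolute thresholds and no personal best PEF"
        )
    pb = float(profile.personal_best_pef)
    return ZoneThresholds(
        green_lower=pb * green_frac,
        yellow_lower=pb * red_frac,
        source=ThresholdSource.FRACTION_OF_PERSONAL_BEST,
    )


def validate_profile(profile: PatientProfile) -> list[str]:
    """Collect human-readable invariant violations (empty list = valid)."""
    problems: list[str] = []
    if not profile.patient_id:
        problems.append("patient_id must be non-empty")
    if profile.enrollment.tzinfo is None:
        problems.append("enrollment timestamp must be timezone-aware (UTC)")
    if profile.personal_best_pef is not None and profile.personal_best_pef <= 0:
        problems.append("personal_best_pef must be positive when present")
    for i, med in enumerate(profile.medications):
        if not med.name:
            problems.append(f"medication #{i} has an empty name")
        if med.med_class not in (MedClass.CONTROLLER, MedClass.RELIEVER):
            problems.append(
                f"medication {med.name!r} has invalid class {med.med_class!r}"
            )
    th = profile.thresholds
    if th is not None and not th.is_valid():
        problems.append(
            f"thresholds must satisfy green_lower > yellow_lower > 0 "
            f"(got green_lower={th.green_lower}, yellow_lower={th.yellow_lower})"
        )
    if profile.baseline_act is not None and not 5 <= profile.baseline_act <= 25:
        problems.append(
            f"baseline ACT score {profile.baseline_act} outside the "
            "instrument's range [5, 25]"
        )
    if not isinstance(profile.reminder_time, time):
        problems.append("reminder_time must be a valid 24-h clock time")
    try:
        ZoneInfo(profile.tz)
    except Exception:
        problems.append(f"unknown timezone {profile.tz!r}")
    plan = profile.action_plan
    if plan is not None:
        acting = {Zone.GREEN, Zone.YELLOW, Zone.RED}
        if set(plan.instructions) != acting:
            problems.append(
                "action plan must have exactly one instruction record per "
                "zone (green, yellow, red)"
            )
    return problems


def validate_cohort(profiles: Sequence[PatientProfile]) -> list[str]:
    """Per-profile violations plus cohort-level patient-id uniqueness."""
    problems: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        problems.extend(f"{p.patient_id}: {v}" for v in validate_profile(p))
        if p.patient_id in seen:
            problems.append(f"duplicate patient_id {p.patient_id!r} in cohort")
        seen.add(p.patient_id)
    return problems


# ---------------------------------------------------------------------------
# JSON serialization (one cohort file: array of profile objects, each
# embedding its action plan)
# ---------------------------------------------------------------------------

def _plan_to_obj(plan: ActionPlan) -> dict:
    return {
        "requires_pef": plan.requires_pef,
        "zones": [
            {
                "zone": ins.zone.value,
                "instructions": ins.instructions,
                "medication_adjustments": [list(t) for t in ins.medication_adjustments],
            }
            for ins in plan.instructions.values()
        ],
    }


def _plan_from_obj(obj: dict) -> ActionPlan:
    return ActionPlan(
        instructions={
            Zone(z["zone"]): ZoneInstruction(
                Zone(z["zone"]),
                z["instructions"],
                tuple(tuple(t) for t in z.get("medication_adjustments", [])),
            )
            for z in obj["zones"]
        },
        requires_pef=bool(obj.get("requires_pef", False)),
    )


def profile_to_obj(profile: PatientProfile) -> dict:
    obj = {
        "patient_id": profile.patient_id,
        "enrollment": profile.enrollment.isoformat(),
        "personal_best_pef": profile.personal_best_pef,
        "medications": [
            {"name": m.name, "med_class": m.med_class.value, "schedule": m.schedule}
            for m in profile.medications
        ],
        "thresholds": None
        if profile.thresholds is None
        else {
            "green_lower": profile.thresholds.green_lower,
            "yellow_lower": profile.thresholds.yellow_lower,
            "source": profile.thresholds.source.value,
        },
        "action_plan": None
        if profile.action_plan is None
        else _plan_to_obj(profile.action_plan),
        "reminder_time": profile.reminder_time.isoformat(timespec="minutes"),
        "email_enabled": profile.email_enabled,
        "tz": profile.tz,
        "age_group": None if profile.age_group is None else profile.age_group.value,
        "college_educated": profile.college_educated,
        "has_smartphone": profile.has_smartphone,
        "baseline_act": profile.baseline_act,
    }
    return obj


def profile_from_obj(obj: dict) -> PatientProfile:
    return PatientProfile(
        patient_id=obj["patient_id"],
        enrollment=datetime.fromisoformat(obj["enrollment"]),
        personal_best_pef=obj.get("personal_best_pef"),
        medications=tuple(
            Medication(m["name"], MedClass(m["med_class"]), m.get("schedule", ""))
            for m in obj.get("medications", [])
        ),
        thresholds=None
        if obj.get("thresholds") is None
        else ZoneThresholds(
            green_lower=obj["thresholds"]["green_lower"],
            yellow_lower=obj["thresholds"]["yellow_lower"],
            source=ThresholdSource(obj["thresholds"].get("source", "absolute")),
        ),
        action_plan=None
        if obj.get("action_plan") is None
        else _plan_from_obj(obj["action_plan"]),
        reminder_time=time.fromisoformat(obj.get("reminder_time", "19:00")),
        email_enabled=bool(obj.get("email_enabled", True)),
        tz=obj.get("tz", DEFAULT_TZ),
        age_group=None if obj.get("age_group") is None else AgeGroup(obj["age_group"]),
        college_educated=obj.get("college_educated"),
        has_smartphone=obj.get("has_smartphone"),
        baseline_act=obj.get("baseline_act"),
    )


def save_cohort(profiles: Iterable[PatientProfile], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([profile_to_obj(p) for p in profiles], indent=1) + "\n"
    )


def load_cohort(path: str | Path) -> list[PatientProfile]:
    return [profile_from_obj(o) for o in json.loads(Path(path).read_text())]
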