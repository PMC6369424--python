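"""Rule-based email reminder planner.

Three deterministic email kinds, evaluated per local calendar day at the
profile's reminder clock time (default 19:00):

* **welcome** — once, at enrollment;
* **adherence** — daily, whenever at least one controller medication is
  prescribed, with no cap;
* **check-in** — after every 7 consecutive local days without a login
  (re-sent every further 7 days of continued inactivity).

Adherence and check-in bodies rotate through a message pool of ~30 texts,
drawn uniformly at random but never repeating the immediately preceding
body, to mitigate reminder fatigue.  Planning is fully deterministic given
(profile, log, horizon, pool seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .event_log import EventLog, EventRecord, EventType, filter_events
from .profiles import PatientProfile

__all__ = [
    "EmailKind",
    "EmailEvent",
    "MessagePool",
    "default_message_pool",
    "select_body",
    "plan_reminders",
    "emails_to_events",
]


class EmailKind(str, Enum):
    WELCOME = "welcome"
    ADHERENCE = "adherence"
    CHECK_IN = "check_in"


@dataclass(frozen=True)
class EmailEvent:
    patient_id: str
    timestamp: datetime  # UTC
    email_kind: EmailKind
    message_id: int


@dataclass(frozen=True)
class MessagePool:
    """Rotating reminder bodies; ``rng_seed`` fixes the rotation."""

    bodies: tuple[str, ...]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bodies) < 1:
            raise ValueError("message pool must contain at least one body")


_OPENERS = [
    "Quick reminder:",
    "Evening check:",
    "Don't forget —",
    "A nudge from your asthma plan:",
    "Daily habit:",
    "Staying on track:",
]
_CORES = [
    "take your controller medication tonight",
    "your controller inhaler keeps airway inflammation down",
    "controller medication works best when taken every day",
    "a minute now for your controller dose pays off all week",
    "keep your asthma in the green zone with tonight's dose",
]


def default_message_pool(size: int = 30, rng_seed: int = 0) -> MessagePool:
    """Build the default pool of ~30 distinct reminder bodies."""
    bodies = [f"{o} {c}." for o in _OPENERS for c in _CORES][:size]
    if len(bodies) < size:  # pragma: no cover - only for size > 30
        bodies += [f"Reminder {i}: time for your controller medication." for i in range(len(bodies), size)]
    return MessagePool(tuple(bodies), rng_seed=rng_seed)


def select_body(
    pool: MessagePool,
    rng: np.random.Generator,
    previous: Optional[int] = None,
) -> int:
    """Draw a message id uniformly, excluding the immediately previous one."""
    n = len(pool.bodies)
    if n == 1:
        return 0
    if previous is None or not 0 <= previous < n:
        return int(rng.integers(n))
    draw = int(rng.integers(n - 1))
    return draw if draw < previous else draw + 1


def _patient_rng(pool: MessagePool, patient_id: str) -> np.random.Generator:
    # Stable per-patient substream: independent of cohort iteration order.
    key = zlib.crc32(patient_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([pool.rng_seed, key]))


def plan_reminders(
    profile: PatientProfile,
    log: EventLog,
    horizon: tuple[datetime, datetime],
    pool: Optional[MessagePool] = None,
) -> list[EmailEvent]:
    """Plan all emails for one patient over ``[start, end)``.

    For a fully inactive patient with a controller medication and the
    horizon starting at enrollment, the plan over D days contains exactly
    ``1 + D + floor(D/7)`` emails (1 welcome, D adherence, a check-in on
    every 7th day of continued inactivity).

    A disabled email preference yields an empty plan.
    """
    if not profile.email_enabled:
        return []
    if pool is None:
        pool = default_message_pool()
    start, end = horizon
    if start >= end:
        return []
    rng = _patient_rng(pool, profile.patient_id)
    tzinfo = profile.tzinfo

    login_days = {
        r.timestamp.astimezone(tzinfo).date()
        for r in filter_events(log, EventType.LOGIN, patient_id=profile.patient_id)
    }
    has_controller = profile.has_controller()
    enroll_day = profile.enrollment.astimezone(tzinfo).date()

    emails: list[EmailEvent] = []
    if start <= profile.enrollment < end:
        emails.append(
            EmailEvent(profile.patient_id, profile.enrollment, EmailKind.WELCOME, 0)
        )

    previous: Optional[int] = None
    last_checkin: Optional[date] = None
    day = start.astimezone(tzinfo).date()
    end_day = (end - timedelta(microseconds=1)).astimezone(tzinfo).date()
    while day <= end_day:
        send_at = datetime.combine(day, profile.reminder_time, tzinfo).astimezone(
            timezone.utc
        )
        if start <= send_at < end and day >= enroll_day:
            if has_controller:
                previous = select_body(pool, rng, previous)
                emails.append(
                    EmailEvent(profile.patient_id, send_at, EmailKind.ADHERENCE, previous)
                )
            inactivity_window = [day - timedelta(days=k) for k in range(7)]
            window_in_study = day - timedelta(days=6) >= enroll_day
            no_login = not any(d in login_days for d in inactivity_window)
            not_recent = last_checkin is None or (day - last_checkin).days >= 7
            if window_in_study and no_login and not_recent:
                previous = select_body(pool, rng, previous)
                emails.append(
                    EmailEvent(profile.patient_id, send_at, EmailKind.CHECK_IN, previous)
                )
                last_checkin = day
        day += timedelta(days=1)
    emails.sort(key=lambda e: (e.timestamp, e.email_kind.value))
    return emails


def emails_to_events(emails: Sequence[EmailEvent]) -> list[EventRecord]:
    """Represent planned emails as ``email_sent`` log events."""
    return [
        EventRecord(
            patient_id=e.patient_id,
            timestamp=e.timestamp,
            event_type=EventType.EMAIL_SENT,
            payload={"email_kind": e.email_kind.value, "message_id": e.message_id},
        )
        for e in emails
    ]
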