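"""Append-only, time-stamped, typed event store with file round-trip.

Every platform interaction — logins, journal reports, medication and peak
flow reports, zone calculations, outgoing emails, action-plan resets, and
clinic visits — is one :class:`EventRecord` keyed by patient id and a UTC
timestamp.  The log serializes losslessly to CSV (header row, ISO-8601
timestamps, payload as a JSON-encoded column) and to JSON-lines (one event
object per line).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

from .journal import JournalEntry

__all__ = [
    "EventType",
    "EventRecord",
    "EventLog",
    "EventLogError",
    "append_event",
    "filter_events",
    "read_events",
    "write_events",
    "journal_event",
    "journal_entries_from_log",
]

CSV_COLUMNS = ["patient_id", "timestamp", "event_type", "payload"]


class EventType(str, Enum):
    LOGIN = "login"
    JOURNAL = "journal"
    MEDICATION_REPORT = "medication_report"
    PEAKFLOW_REPORT = "peakflow_report"
    ZONE_CALC = "zone_calc"
    EMAIL_SENT = "email_sent"
    RESET = "reset"
    CLINIC_VISIT = "clinic_visit"


class EventLogError(ValueError):
    """Malformed event data; carries the offending line/field when parsing."""


@dataclass(frozen=True, slots=True)
class EventRecord:
    patient_id: str
    timestamp: datetime  # timezone-aware UTC
    event_type: EventType
    payload: Mapping[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.patient_id:
            raise EventLogError("patient_id must be non-empty")
        if not isinstance(self.event_type, EventType):
            raise EventLogError(f"unknown event_type {self.event_type!r}")
        if self.timestamp.tzinfo is None:
            raise EventLogError("event timestamps must be timezone-aware UTC")


@dataclass(frozen=True)
class EventLog:
    """Immutable ordered sequence of events with optional observation window.

    When a window ``(start, end)`` is set, appends outside it are rejected
    (half-open: start inclusive, end exclusive).
    """

    records: tuple[EventRecord, ...] = ()
    cohort_id: str = "cohort"
    window: Optional[tuple[datetime, datetime]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def append_event(log: EventLog, record: EventRecord) -> EventLog:
    """Return a new log with ``record`` appended; the original is unchanged."""
    record.validate()
    if log.window is not None:
        start, end = log.window
        if not start <= record.timestamp < end:
            raise EventLogError(
                f"event timestamp {record.timestamp.isoformat()} outside "
                f"observation window [{start.isoformat()}, {end.isoformat()})"
            )
    return replace(log, records=log.records + (record,))


def extend_log(log: EventLog, records: Iterable[EventRecord]) -> EventLog:
    recs = tuple(records)
    for r in recs:
        r.validate()
    return replace(log, records=log.records + recs)


def filter_events(
    log: EventLog,
    event_type: Optional[EventType] = None,
    interval: Optional[tuple[datetime, datetime]] = None,
    patient_id: Optional[str] = None,
) -> EventLog:
    """Select records matching type / half-open interval [start, end) / patient."""
    if interval is not None and interval[0] > interval[1]:
        raise ValueError("interval start must be <= end")

    def keep(r: EventRecord) -> bool:
        if event_type is not None and r.event_type != event_type:
            return False
        if interval is not None and not interval[0] <= r.timestamp < interval[1]:
            return False
        if patient_id is not None and r.patient_id != patient_id:
            return False
        return True

    return replace(log, records=tuple(r for r in log.records if keep(r)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _parse_timestamp(raw: str, lineno: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw)
    except ValueError as exc:
        raise EventLogError(f"line {lineno}: bad timestamp {raw!r}: {exc}") from None
    if ts.tzinfo is None:
        raise EventLogError(f"line {lineno}: timestamp {raw!r} lacks a UTC offset")
    return ts.astimezone(timezone.utc)


def _record_from_obj(obj: Mapping[str, Any], lineno: int) -> EventRecord:
    for key in ("patient_id", "timestamp", "event_type"):
        if key not in obj or obj[key] in (None, ""):
            raise EventLogError(f"line {lineno}: missing field {key!r}")
    try:
        etype = EventType(obj["event_type"])
    except ValueError:
        raise EventLogError(
            f"line {lineno}: unknown event_type {obj['event_type']!r}"
        ) from None
    return EventRecord(
        patient_id=str(obj["patient_id"]),
        timestamp=_parse_timestamp(str(obj["timestamp"]), lineno),
        event_type=etype,
        payload=dict(obj.get("payload") or {}),
    )


def write_events(log: EventLog, path: str | Path, format: str = "jsonl") -> None:
    """Write the log; ``read_events(write_events(log))`` is the identity on records."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            for r in log.records:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": r.patient_id,
                            "timestamp": r.timestamp.isoformat(),
                            "event_type": r.event_type.value,
                            "payload": dict(r.payload),
                        },
                        separators=(",", ":"),
                        sort_keys=True,
                    )
                    + "\n"
                )
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for r in log.records:
                writer.writerow(
                    [
                        r.patient_id,
                        r.timestamp.isoformat(),
                        r.event_type.value,
                        json.dumps(dict(r.payload), separators=(",", ":"), sort_keys=True),
                    ]
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")


def read_events(
    path: str | Path,
    format: str = "jsonl",
    cohort_id: str = "cohort",
    window: Optional[tuple[datetime, datetime]] = None,
) -> EventLog:
    """Read an event log file; malformed rows raise with line number and field."""
    path = Path(path)
    records: list[EventRecord] = []
    if format == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise EventLogError(f"line {lineno}: invalid JSON: {exc}") from None
                records.append(_record_from_obj(obj, lineno))
    elif format == "csv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                return EventLog((), cohort_id, window)
            missing = [c for c in CSV_COLUMNS if c not in header]
            if missing:
                raise EventLogError(
                    f"line 1: CSV header missing column(s) {', '.join(missing)}"
                )
            idx = {c: header.index(c) for c in CSV_COLUMNS}
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) < len(header):
                    raise EventLogError(f"line {lineno}: expected {len(header)} fields")
                try:
                    payload = json.loads(row[idx["payload"]]) if row[idx["payload"]] else {}
                except json.JSONDecodeError as exc:
                    raise EventLogError(
                        f"line {lineno}: field 'payload' is not valid JSON: {exc}"
                    ) from None
                records.append(
                    _record_from_obj(
                        {
                            "patient_id": row[idx["patient_id"]],
                            "timestamp": row[idx["timestamp"]],
                            "event_type": row[idx["event_type"]],
                            "payload": payload,
                        },
                        lineno,
                    )
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")
    return EventLog(tuple(records), cohort_id, window)


# ---------------------------------------------------------------------------
# Journal payload bridging
# ---------------------------------------------------------------------------

def journal_event(entry: JournalEntry) -> EventRecord:
    """Wrap a journal entry as a ``journal`` event."""
    return EventRecord(
        patient_id=entry.patient_id,
        timestamp=entry.timestamp,
        event_type=EventType.JOURNAL,
        payload={
            "daytime_symptoms": entry.daytime_symptoms,
            "night_waking": entry.night_waking,
            "activity_limitation": entry.activity_limitation,
            "severe_flag": entry.severe_flag,
            "reliever_doses": entry.reliever_doses,
            "triggers": list(entry.triggers),
            "pef": entry.pef,
        },
    )


def journal_entries_from_log(
    log: EventLog, patient_id: Optional[str] = None
) -> list[JournalEntry]:
    """Reconstruct journal entries from ``journal`` events."""
    entries = []
    for r in log.records:
        if r.event_type != EventType.JOURNAL:
            continue
        if patient_id is not None and r.patient_id != patient_id:
            continue
        p = r.payload
        entries.append(
            JournalEntry(
                patient_id=r.patient_id,
                timestamp=r.timestamp,
                daytime_symptoms=bool(p.get("daytime_symptoms", False)),
                night_waking=bool(p.get("night_waking", False)),
                activity_limitation=bool(p.get("activity_limitation", False)),
                severe_flag=bool(p.get("severe_flag", False)),
                reliever_doses=int(p.get("reliever_doses", 0)),
                triggers=tuple(p.get("triggers", ())),
                pef=p.get("pef"),
            )
        )
    return entries
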