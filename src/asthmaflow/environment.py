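"""Air Quality Health Index (AQHI) banding and risk-reduction messaging.

The AQHI is Canada's 1-10(+) communication scale for short-term air-quality
health risk.  Readings are supplied from a local CSV file (columns:
``location,timestamp,value``); the live feed is out of scope.  Banding uses
the public Health Canada categories: 1-3 low, 4-6 moderate, 7-10 high,
above 10 very high.  Messages are configuration; asthma-oriented defaults
are shipped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

__all__ = ["AqhiBand", "AqhiReading", "DEFAULT_MESSAGES", "aqhi_band", "read_aqhi_csv"]


class AqhiBand(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


DEFAULT_MESSAGES: Mapping[AqhiBand, str] = {
    AqhiBand.LOW: (
        "Air quality poses little risk today. Enjoy your usual outdoor activities."
    ),
    AqhiBand.MODERATE: (
        "Consider reducing strenuous outdoor activity if you notice coughing "
        "or throat irritation; keep your reliever inhaler with you."
    ),
    AqhiBand.HIGH: (
        "Reduce or reschedule strenuous outdoor activity; people with asthma "
        "should follow their action plan and keep their reliever close."
    ),
    AqhiBand.VERY_HIGH: (
        "Avoid strenuous outdoor activity. Stay indoors if you experience "
        "symptoms and follow your asthma action plan."
    ),
}


@dataclass(frozen=True)
class AqhiReading:
    location: str
    timestamp: datetime
    value: float

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ValueError(f"AQHI value must be >= 1, got {self.value}")


def aqhi_band(
    value: float,
    messages: Optional[Mapping[AqhiBand, str]] = None,
) -> tuple[AqhiBand, str]:
    """Band an AQHI value and return the band's health message.

    The banding is a total, monotone step function of the value.
    """
    if value < 1:
        raise ValueError(f"invalid AQHI reading: {value} (scale starts at 1)")
    if messages is None:
        messages = DEFAULT_MESSAGES
    if value <= 3:
        band = AqhiBand.LOW
    elif value <= 6:
        band = AqhiBand.MODERATE
    elif value <= 10:
        band = AqhiBand.HIGH
    else:
        band = AqhiBand.VERY_HIGH
    return band, messages[band]


def read_aqhi_csv(path: str | Path) -> list[AqhiReading]:
    """Read local AQHI readings (columns: location, timestamp, value)."""
    readings = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"location", "timestamp", "value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"AQHI file must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row["timestamp"])
                if ts.tzinfo is None:
                    ts = ts.replace(tzinfo=timezone.utc)
                readings.append(
                    AqhiReading(row["location"], ts, float(row["value"]))
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return readings
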