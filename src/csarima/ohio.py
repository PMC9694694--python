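"""Reader for the OhioT1DM XML layout.

The clinical dataset itself is access-restricted; this reader is provided for
users who hold a copy.  It consumes the ``<glucose_level>``, ``<meal>``,
``<bolus>`` and ``<basal>`` elements of a subject file and produces the same
``(GlucoseSeries, EventLog)`` pair as the CSV readers, with timestamps
snapped to the 5-minute grid.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

from .io_segmentation import (
    SAMPLING_INTERVAL,
    EventLog,
    GlucoseSeries,
    InsulinEvent,
    MealEvent,
    ParseError,
    snap_to_grid,
)

_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


def _parse_ts(raw: str) -> pd.Timestamp:
    try:
        return pd.Timestamp(pd.to_datetime(raw, format=_TS_FORMAT))
    except (ValueError, TypeError):
        try:
            return pd.Timestamp(raw)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"unparseable timestamp {raw!r}") from exc


def read_ohio_xml(path) -> tuple[GlucoseSeries, EventLog]:
    """Read one OhioT1DM subject XML file into a glucose series and event log."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc

    samples: list[tuple[int, float]] = []
    for ev in root.findall("./glucose_level/event"):
        ts = _parse_ts(ev.get("ts"))
        samples.append((snap_to_grid(ts), float(ev.get("value"))))
    if not samples:
        raise ParseError(f"{path}: no glucose_level events")
    first = min(s for s, _ in samples)
    last = max(s for s, _ in samples)
    values = np.full(last - first + 1, np.nan)
    for slot, value in samples:  # duplicates: keep the last record
        values[slot - first] = value
    step = int(SAMPLING_INTERVAL.total_seconds())
    series = GlucoseSeries(
        start_time=pd.Timestamp(first * step, unit="s"),
        values=values,
        missing_mask=np.isnan(values),
    )

    meals = []
    for ev in root.findall("./meal/event"):
        carbs = ev.get("carbs")
        meals.append(
            MealEvent(
                _parse_ts(ev.get("ts")),
                float(carbs) if carbs not in (None, "") else None,
                ev.get("type", "") or "",
            )
        )
    boluses = [
        InsulinEvent(_parse_ts(ev.get("ts_begin") or ev.get("ts")), float(ev.get("dose")))
        for ev in root.findall("./bolus/event")
    ]
    basal = [
        InsulinEvent(_parse_ts(ev.get("ts")), float(ev.get("value")))
        for ev in root.findall("./basal/event")
    ]
    return series, EventLog(
        tuple(sorted(meals, key=lambda e: e.time)),
        tuple(sorted(boluses, key=lambda e: e.time)),
        tuple(sorted(basal, key=lambda e: e.time)),
    )
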