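"""Chart-event data model, CSV I/O, unit canonicalization and plausibility filtering.

A *chart event* is one timestamped measurement of one clinical parameter for
one hospital admission — the long-format record shape used by ICU electronic
health records.  Six parameters are modelled: systolic arterial blood pressure
(SABP), Glasgow Coma Scale (GCS), respiratory rate (RR), heart rate (HR), body
temperature (BT) and white blood cell count (WBC).

All downstream analysis assumes canonical units:

==========  =====================  ==========================
parameter   canonical unit         notes
==========  =====================  ==========================
SABP        mmHg
GCS         score                  integer scale, clinically 3-15
RR          breaths/min
HR          beats/min
BT          °F                     screening cutoffs are quoted in °F
WBC         10³/mm³                so a count of 12,000/mm³ reads 12.0
==========  =====================  ==========================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "ChartEvent",
    "PlausibilityRanges",
    "ExcludedEvent",
    "ChartFormatError",
    "UnitError",
    "CANONICAL_UNITS",
    "DEFAULT_PLAUSIBILITY",
    "CSV_COLUMNS",
    "to_canonical",
    "read_chart_events",
    "write_chart_events",
    "filter_plausible",
    "events_to_frame",
]


class Parameter(str, Enum):
    """The six screening parameters."""

    SABP = "SABP"
    GCS = "GCS"
    RR = "RR"
    HR = "HR"
    BT = "BT"
    WBC = "WBC"


CANONICAL_UNITS: Mapping[Parameter, str] = {
    Parameter.SABP: "mmHg",
    Parameter.GCS: "score",
    Parameter.RR: "breaths/min",
    Parameter.HR: "beats/min",
    Parameter.BT: "degF",
    Parameter.WBC: "10^3/mm^3",
}

CSV_COLUMNS = ("admission_id", "chart_time", "parameter", "value", "unit")


class ChartFormatError(ValueError):
    """A chart-event file or row violates the expected format."""


class UnitError(ValueError):
    """A (parameter, unit) pair has no registered conversion."""


def _normalize_unit(unit: str) -> str:
    return unit.strip().lower().replace(" ", "").replace("°", "deg")


# Conversion callables map a value in the source unit to the canonical unit.
_IDENTITY: Callable[[float], float] = lambda v: v

_UNIT_TABLE: dict[Parameter, dict[str, Callable[[float], float]]] = {
    Parameter.SABP: {"": _IDENTITY, "mmhg": _IDENTITY},
    Parameter.GCS: {"": _IDENTITY, "score": _IDENTITY, "points": _IDENTITY},
    Parameter.RR: {
        "": _IDENTITY,
        "breaths/min": _IDENTITY,
        "breaths/minute": _IDENTITY,
        "insp/min": _IDENTITY,
        "/min": _IDENTITY,
        "bpm": _IDENTITY,
    },
    Parameter.HR: {
        "": _IDENTITY,
        "beats/min": _IDENTITY,
        "beats/minute": _IDENTITY,
        "/min": _IDENTITY,
        "bpm": _IDENTITY,
    },
    Parameter.BT: {
        "": _IDENTITY,
        "degf": _IDENTITY,
        "f": _IDENTITY,
        "fahrenheit": _IDENTITY,
        "degc": lambda v: v * 9.0 / 5.0 + 32.0,
        "c": lambda v: v * 9.0 / 5.0 + 32.0,
        "celsius": lambda v: v * 9.0 / 5.0 + 32.0,
    },
    Parameter.WBC: {
        "": _IDENTITY,
        "10^3/mm^3": _IDENTITY,
        "10^3/mm3": _IDENTITY,
        "k/ul": _IDENTITY,
        "x10^3/mm^3": _IDENTITY,
        "10^3/ul": _IDENTITY,
        "/mm^3": lambda v: v / 1000.0,
        "/mm3": lambda v: v / 1000.0,
        "/ul": lambda v: v / 1000.0,
        "cells/mm3": lambda v: v / 1000.0,
    },
}


def to_canonical(value: float, source_unit: str, parameter: Parameter) -> float:
    """Convert ``value`` from ``source_unit`` to the parameter's canonical unit.

    Raises :class:`UnitError` when the (parameter, unit) pair is not in the
    conversion table.  An empty unit string is treated as already canonical.
    """
    key = _normalize_unit(source_unit)
    table = _UNIT_TABLE[Parameter(parameter)]
    if key not in table:
        raise UnitError(
            f"no conversion registered for unit {source_unit!r} of parameter "
            f"{Parameter(parameter).value}"
        )
    return table[key](float(value))


@dataclass(frozen=True, slots=True)
class ChartEvent:
    """One timestamped measurement, value already in canonical units.

    ``chart_time`` is truncated to minute resolution on construction;
    timestamps are timezone-naive.
    """

    admission_id: str
    chart_time: datetime
    parameter: Parameter
    value: float
    source_unit: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value {self.value!r} for {self.parameter}")
        object.__setattr__(self, "parameter", Parameter(self.parameter))
        t = self.chart_time
        if t.second or t.microsecond:
            object.__setattr__(self, "chart_time", t.replace(second=0, microsecond=0))


@dataclass(frozen=True)
class PlausibilityRanges:
    """Closed per-parameter interval [lo, hi] of biologically plausible values."""

    ranges: Mapping[Parameter, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [p for p in Parameter if p not in self.ranges]
        if missing:
            raise ValueError(f"plausibility ranges missing parameters: {missing}")
        for p, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {p}: [{lo}, {hi}]")

    def __getitem__(self, parameter: Parameter) -> tuple[float, float]:
        return self.ranges[Parameter(parameter)]

    def contains(self, parameter: Parameter, value: float) -> bool:
        lo, hi = self[parameter]
        return lo <= value <= hi

    def with_overrides(
        self, overrides: Mapping[Parameter, tuple[float, float]]
    ) -> "PlausibilityRanges":
        merged = dict(self.ranges)
        merged.update({Parameter(p): (float(lo), float(hi)) for p, (lo, hi) in overrides.items()})
        return PlausibilityRanges(merged)


#: Generous physiologic envelopes intended only to strip data-entry artifacts.
DEFAULT_PLAUSIBILITY = PlausibilityRanges(
    {
        Parameter.SABP: (20.0, 300.0),
        Parameter.GCS: (3.0, 15.0),
        Parameter.RR: (0.0, 80.0),
        Parameter.HR: (0.0, 300.0),
        Parameter.BT: (77.0, 110.0),
        Parameter.WBC: (0.0, 200.0),
    }
)


@dataclass(frozen=True)
class ExcludedEvent:
    """A chart event rejected by the plausibility filter, with the violated bound."""

    event: ChartEvent
    reason: str
    bound: float
    side: str  # "below" or "above"


def filter_plausible(
    events: Sequence[ChartEvent],
    ranges: PlausibilityRanges = DEFAULT_PLAUSIBILITY,
) -> tuple[list[ChartEvent], list[ExcludedEvent]]:
    """Split events into biologically plausible and excluded.

    Values outside the closed interval for their parameter are excluded as
    presumed data-entry mistakes; nothing is imputed.  Order is preserved
    within both outputs and the two outputs partition the input.
    """
    kept: list[ChartEvent] = []
    excluded: list[ExcludedEvent] = []
    for ev in events:
        lo, hi = ranges[ev.parameter]
        if ev.value < lo:
            excluded.append(
                ExcludedEvent(ev, f"{ev.parameter.value}={ev.value} below lower bound {lo}", lo, "below")
            )
        elif ev.value > hi:
            excluded.append(
                ExcludedEvent(ev, f"{ev.parameter.value}={ev.value} above upper bound {hi}", hi, "above")
            )
        else:
            kept.append(ev)
    return kept, excluded


def _parse_row(
    admission_id: object, chart_time: object, parameter: object, value: object, unit: object
) -> ChartEvent:
    param = Parameter(str(parameter).strip())
    ts = pd.Timestamp(str(chart_time))
    if pd.isna(ts):
        raise ValueError(f"unparseable chart_time {chart_time!r}")
    canon = to_canonical(float(value), "" if pd.isna(unit) else str(unit), param)
    return ChartEvent(
        admission_id=str(admission_id),
        chart_time=ts.to_pydatetime(),
        parameter=param,
        value=canon,
        source_unit="" if pd.isna(unit) else str(unit),
    )


def read_chart_events(path: str | Path, strict: bool = True) -> list[ChartEvent]:
    """Read a long-format chart-event CSV into canonical-unit events.

    The file must carry a header naming the five columns
    ``admission_id, chart_time, parameter, value, unit``.  In strict mode a
    malformed row raises :class:`ChartFormatError` identifying the row; in
    lenient mode malformed rows are logged and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ChartFormatError(f"{path}: missing required column(s) {missing}")
    events: list[ChartEvent] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        try:
            events.append(
                _parse_row(row.admission_id, row.chart_time, row.parameter, row.value, row.unit)
            )
        except (ValueError, UnitError) as exc:
            if strict:
                raise ChartFormatError(f"{path}: row {idx + 2}: {exc}") from exc
            logger.warning("skipping row %d of %s: %s", idx + 2, path, exc)
    return events


def events_to_frame(events: Iterable[ChartEvent]) -> pd.DataFrame:
    """Long-format DataFrame view of an event sequence (canonical units)."""
    return pd.DataFrame(
        {
            "admission_id": [e.admission_id for e in events],
            "chart_time": [e.chart_time for e in events],
            "parameter": [e.parameter.value for e in events],
            "value": [e.value for e in events],
        }
    )


def write_chart_events(events: Sequence[ChartEvent], path: str | Path) -> None:
    """Write events as the chart-event CSV dialect, in canonical units."""
    frame = events_to_frame(events)
    frame["unit"] = [CANONICAL_UNITS[e.parameter] for e in events]
    frame["chart_time"] = [e.chart_time.isoformat() for e in events]
    frame.to_csv(path, index=False, columns=list(CSV_COLUMNS))
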