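"""Simultaneous-observation alignment and the first-observation phase.

Screening scores are only defined when every parameter of a criteria set was
charted at the same time, so analyses keep exactly those chart times.  Because
charting is asynchronous in real ICUs, an optional tolerance window groups
timestamps into bins before requiring completeness; the default tolerance of
zero demands exact minute-resolution equality.

The *first-observation phase* restricts the cohort to each admission's
earliest record — per parameter, or per complete aligned snapshot — as a
sensitivity analysis against length-of-stay over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .chartio import ChartEvent, Parameter

__all__ = ["AlignedObservation", "align", "first_per_admission"]

_EPOCH = datetime(2000, 1, 1)


@dataclass(frozen=True)
class AlignedObservation:
    """A complete simultaneous snapshot of a parameter set at one chart time."""

    admission_id: str
    chart_time: datetime
    values: Mapping[Parameter, float]

    def __post_init__(self) -> None:
        for p, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for {p} at {self.chart_time}")


def _resolve_time(t: datetime, tolerance: timedelta) -> datetime:
    if tolerance <= timedelta(0):
        return t
    n = (t - _EPOCH) // tolerance
    return _EPOCH + n * tolerance


def align(
    events: Sequence[ChartEvent],
    parameters: Iterable[Parameter],
    tolerance: timedelta = timedelta(0),
) -> list[AlignedObservation]:
    """Build complete simultaneous observations for ``parameters``.

    Timestamps are resolved to bins of width ``tolerance`` (exact timestamps
    when zero).  Duplicate values of one parameter at one resolved time are
    averaged, which is deterministic and independent of input order.  Only
    (admission, resolved time) pairs carrying *all* requested parameters are
    emitted, sorted by (admission_id, chart_time).
    """
    params = [Parameter(p) for p in parameters]
    if not params:
        raise ValueError("parameter set must be non-empty")
    if len(set(params)) != len(params):
        raise ValueError("parameter set contains duplicates")
    relevant = [e for e in events if e.parameter in params]
    if not relevant:
        return []
    frame = pd.DataFrame(
        {
            "admission_id": [e.admission_id for e in relevant],
            "time": [_resolve_time(e.chart_time, tolerance) for e in relevant],
            "parameter": [e.parameter.value for e in relevant],
            "value": [e.value for e in relevant],
        }
    )
    wide = (
        frame.groupby(["admission_id", "time", "parameter"])["value"]
        .mean()
        .unstack("parameter")
    )
    wide = wide.dropna(subset=[p.value for p in params]).sort_index()
    out: list[AlignedObservation] = []
    for (adm, t), row in wide.iterrows():
        out.append(
            AlignedObservation(
                admission_id=adm,
                chart_time=t.to_pydatetime() if hasattr(t, "to_pydatetime") else t,
                values={p: float(row[p.value]) for p in params},
            )
        )
    return out


def _first_events(events: Sequence[ChartEvent]) -> list[ChartEvent]:
    # earliest event per (admission, parameter); ties at the identical
    # earliest minute are averaged so the result is order-free
    by_key: dict[tuple[str, Parameter], list[ChartEvent]] = {}
    for e in events:
        key = (e.admission_id, e.parameter)
        cur = by_key.get(key)
        if cur is None or e.chart_time < cur[0].chart_time:
            by_key[key] = [e]
        elif e.chart_time == cur[0].chart_time:
            cur.append(e)
    out: list[ChartEvent] = []
    for (adm, param), group in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        value = sum(g.value for g in group) / len(group)
        out.append(
            ChartEvent(
                admission_id=adm,
                chart_time=group[0].chart_time,
                parameter=param,
                value=value,
                source_unit=group[0].source_unit,
            )
        )
    return out


def _first_aligned(observations: Sequence[AlignedObservation]) -> list[AlignedObservation]:
    # earliest aligned observation per admission; exact ties broken by the
    # lexicographically first value tuple
    best: dict[str, AlignedObservation] = {}
    for obs in observations:
        cur = best.get(obs.admission_id)
        if cur is None or obs.chart_time < cur.chart_time:
            best[obs.admission_id] = obs
        elif obs.chart_time == cur.chart_time:
            key_new = tuple(obs.values[p] for p in sorted(obs.values, key=lambda q: q.value))
            key_cur = tuple(cur.values[p] for p in sorted(cur.values, key=lambda q: q.value))
            if key_new < key_cur:
                best[obs.admission_id] = obs
    return [best[a] for a in sorted(best)]


def first_per_admission(
    records: Sequence[ChartEvent] | Sequence[AlignedObservation],
    mode: str = "per_parameter",
):
    """Restrict to each admission's earliest record(s).

    ``per_parameter`` takes the earliest chart event of every
    (admission, parameter) pair and expects chart events; ``first_aligned``
    takes the earliest complete snapshot per admission and expects aligned
    observations.
    """
    if mode not in ("per_parameter", "first_aligned"):
        raise ValueError(f"unknown first-observation mode {mode!r}")
    if not records:
        return []
    if mode == "per_parameter":
        if not isinstance(records[0], ChartEvent):
            raise TypeError("per_parameter mode expects chart events")
        return _first_events(records)  # type: ignore[arg-type]
    if not isinstance(records[0], AlignedObservation):
        raise TypeError("first_aligned mode expects aligned observations")
    return _first_aligned(records)  # type: ignore[arg-type]
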