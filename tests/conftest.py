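"""Shared fixtures: tiny hand-built chart-event sequences and CSV writers."""

from __future__ import annotations

from datetime import datetime

import pytest

from sepscreen.chartio import ChartEvent, Parameter

T0 = datetime(2021, 3, 1, 8, 0)


def ev(adm: str, minute: int, param: Parameter, value: float) -> ChartEvent:
    """Shorthand for a canonical-unit event `minute` minutes after T0."""
    return ChartEvent(
        admission_id=adm,
        chart_time=T0.replace(minute=0) if minute == 0 else T0,
        parameter=param,
        value=value,
    )


def ev_at(adm: str, when: datetime, param: Parameter, value: float) -> ChartEvent:
    return ChartEvent(admission_id=adm, chart_time=when, parameter=param, value=value)


@pytest.fixture
def qsofa_complete_events():
    """One admission: complete qSOFA triple at T0, lone RR 30 min later."""
    from datetime import timedelta

    later = T0 + timedelta(minutes=30)
    return [
        ev_at("A1", T0, Parameter.RR, 24.0),
        ev_at("A1", T0, Parameter.GCS, 12.0),
        ev_at("A1", T0, Parameter.SABP, 95.0),
        ev_at("A1", later, Parameter.RR, 26.0),
    ]


@pytest.fixture
def chart_csv(tmp_path):
    """Write a chart-event CSV from (adm, time, param, value, unit) rows."""

    def _write(rows, name="events.csv", header="admission_id,chart_time,parameter,value,unit"):
        path = tmp_path / name
        lines = [header] + [",".join(str(c) for c in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
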