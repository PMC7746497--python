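"""qSOFA (sepsis-3) and SIRS (sepsis-2) screening criteria.

Both screens flag possible sepsis when at least two of their criteria are met
simultaneously.  The boundary conventions differ and are the classic source of
off-by-one errors, so they are encoded explicitly:

* qSOFA cutoffs are **inclusive**: RR ≥ 22 breaths/min, GCS ≤ 13,
  systolic blood pressure ≤ 100 mmHg.
* SIRS cutoffs are **strict**: BT > 100.4 °F or < 96.8 °F, RR > 20 breaths/min,
  HR > 90 beats/min, WBC > 12 or < 4 (×10³/mm³).

A value exactly at a qSOFA threshold therefore meets the criterion, while a
value exactly at a SIRS threshold does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .alignment import AlignedObservation
from .chartio import Parameter

__all__ = [
    "Comparison",
    "CriterionDefinition",
    "CriteriaSet",
    "CriteriaResult",
    "IncompleteObservationError",
    "QSOFA",
    "SIRS",
    "evaluate_criterion",
    "evaluate",
    "criteria_set_from_dict",
]


class Comparison(str, Enum):
    AT_LEAST = "at_least"        # value >= threshold
    AT_MOST = "at_most"          # value <= threshold
    GREATER = "greater"          # value >  threshold
    LESS = "less"                # value <  threshold
    OUTSIDE_BAND = "outside_band"  # value < lo or value > hi (strict)


class IncompleteObservationError(ValueError):
    """An observation lacks a parameter required by the criteria set."""


@dataclass(frozen=True)
class CriterionDefinition:
    """One named threshold predicate on one parameter (canonical units)."""

    name: str
    parameter: Parameter
    comparison: Comparison
    threshold: Optional[float] = None
    band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.comparison is Comparison.OUTSIDE_BAND:
            if self.band is None or self.threshold is not None:
                raise ValueError(f"{self.name}: outside_band requires a band and no threshold")
            lo, hi = self.band
            if not lo < hi:
                raise ValueError(f"{self.name}: band must satisfy lo < hi, got {self.band}")
        else:
            if self.threshold is None or self.band is not None:
                raise ValueError(f"{self.name}: {self.comparison.value} requires a single threshold")

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "parameter": self.parameter.value,
            "comparison": self.comparison.value,
        }
        if self.threshold is not None:
            d["threshold"] = self.threshold
        if self.band is not None:
            d["band"] = list(self.band)
        return d


def evaluate_criterion(defn: CriterionDefinition, value: float) -> bool:
    """Apply the criterion predicate to a canonical-unit value."""
    if not math.isfinite(value):
        raise ValueError(f"{defn.name}: non-finite value {value!r}")
    c = defn.comparison
    if c is Comparison.AT_LEAST:
        return value >= defn.threshold
    if c is Comparison.AT_MOST:
        return value <= defn.threshold
    if c is Comparison.GREATER:
        return value > defn.threshold
    if c is Comparison.LESS:
        return value < defn.threshold
    lo, hi = defn.band  # type: ignore[misc]
    return value < lo or value > hi


@dataclass(frozen=True)
class CriteriaSet:
    """An ordered set of criteria with the ≥ min_met sepsis rule."""

    name: str
    criteria: tuple[CriterionDefinition, ...]
    min_met_for_sepsis: int = 2

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: duplicate criterion names")
        if not 1 <= self.min_met_for_sepsis <= len(self.criteria):
            raise ValueError(
                f"{self.name}: min_met_for_sepsis must be in [1, {len(self.criteria)}]"
            )

    @property
    def parameters(self) -> tuple[Parameter, ...]:
        return tuple(c.parameter for c in self.criteria)

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.criteria)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "min_met_for_sepsis": self.min_met_for_sepsis,
            "criteria": [c.to_dict() for c in self.criteria],
        }


@dataclass(frozen=True)
class CriteriaResult:
    """Outcome of evaluating one criteria set on one aligned observation."""

    set_name: str
    met: tuple[str, ...]
    score: int
    sepsis_flag: bool
    min_met_for_sepsis: int = 2


def evaluate(cset: CriteriaSet, obs: AlignedObservation) -> CriteriaResult:
    """Evaluate every criterion of ``cset`` on one complete observation."""
    met: list[str] = []
    for defn in cset.criteria:
        if defn.parameter not in obs.values:
            raise IncompleteObservationError(
                f"observation at {obs.chart_time} for admission {obs.admission_id} "
                f"lacks parameter {defn.parameter.value} required by {cset.name}"
            )
        if evaluate_criterion(defn, obs.values[defn.parameter]):
            met.append(defn.name)
    score = len(met)
    return CriteriaResult(
        set_name=cset.name,
        met=tuple(met),
        score=score,
        sepsis_flag=score >= cset.min_met_for_sepsis,
        min_met_for_sepsis=cset.min_met_for_sepsis,
    )


def criteria_set_from_dict(d: Mapping) -> CriteriaSet:
    """Deserialize a criteria set (the config-file override format)."""
    criteria = tuple(
        CriterionDefinition(
            name=c["name"],
            parameter=Parameter(c["parameter"]),
            comparison=Comparison(c["comparison"]),
            threshold=c.get("threshold"),
            band=tuple(c["band"]) if "band" in c else None,
        )
        for c in d["criteria"]
    )
    return CriteriaSet(
        name=d["name"],
        criteria=criteria,
        min_met_for_sepsis=int(d.get("min_met_for_sepsis", 2)),
    )


#: Sepsis-3 bedside screen: positive at ≥2 of 3 criteria, inclusive cutoffs.
QSOFA = CriteriaSet(
    name="qSOFA",
    criteria=(
        CriterionDefinition("high_respiratory_rate", Parameter.RR, Comparison.AT_LEAST, 22.0),
        CriterionDefinition("altered_mental_status", Parameter.GCS, Comparison.AT_MOST, 13.0),
        CriterionDefinition("hypotension", Parameter.SABP, Comparison.AT_MOST, 100.0),
    ),
    min_met_for_sepsis=2,
)

#: Sepsis-2 screen: positive at ≥2 of 4 criteria, strict cutoffs.
SIRS = CriteriaSet(
    name="SIRS",
    criteria=(
        CriterionDefinition(
            "abnormal_temperature", Parameter.BT, Comparison.OUTSIDE_BAND, band=(96.8, 100.4)
        ),
        CriterionDefinition("tachypnea", Parameter.RR, Comparison.GREATER, 20.0),
        CriterionDefinition("tachycardia", Parameter.HR, Comparison.GREATER, 90.0),
        CriterionDefinition(
            "abnormal_wbc", Parameter.WBC, Comparison.OUTSIDE_BAND, band=(4.0, 12.0)
        ),
    ),
    min_met_for_sepsis=2,
)
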