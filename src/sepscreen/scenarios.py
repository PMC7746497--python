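"""Sepsis-scenario enumeration, classification and prevalence.

A *scenario* is the exact set of criteria met simultaneously.  With a
positivity rule of ≥2 criteria, a set of n criteria admits 2ⁿ − n − 1
sepsis-positive scenarios (all subsets minus the empty set and the n
singletons): 4 for the three qSOFA criteria, 11 for the four SIRS criteria.
Observations meeting fewer than two criteria fall into the no-sepsis
scenario, so the scenario labels partition the aligned observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chartio import ChartEvent
from .alignment import AlignedObservation
from .criteria import (
    CriteriaResult,
    CriteriaSet,
    CriterionDefinition,
    evaluate,
    evaluate_criterion,
)

__all__ = [
    "ScenarioLabel",
    "NO_SEPSIS",
    "ScenarioPrevalenceTable",
    "PrevalenceResult",
    "enumerate_scenarios",
    "classify",
    "scenario_prevalence",
    "criterion_prevalence",
    "round_percentage",
]


@dataclass(frozen=True, order=True)
class ScenarioLabel:
    """Canonically sorted tuple of met criteria; the empty tuple is no-sepsis."""

    criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        if tuple(sorted(self.criteria)) != self.criteria:
            raise ValueError(f"scenario label must be sorted: {self.criteria}")
        if len(set(self.criteria)) != len(self.criteria):
            raise ValueError(f"scenario label has duplicates: {self.criteria}")

    @property
    def is_sepsis(self) -> bool:
        return bool(self.criteria)

    def __str__(self) -> str:
        return "+".join(self.criteria) if self.criteria else "no_sepsis"


NO_SEPSIS = ScenarioLabel(())


def enumerate_scenarios(criteria_names: Sequence[str], min_met: int) -> list[ScenarioLabel]:
    """All sepsis-positive criterion combinations, then the no-sepsis label.

    Order is deterministic: by subset size ascending, then lexicographic.
    """
    names = list(criteria_names)
    if len(set(names)) != len(names):
        raise ValueError("criteria names must be unique")
    if not 1 <= min_met <= len(names):
        raise ValueError(f"min_met must be in [1, {len(names)}], got {min_met}")
    labels: list[ScenarioLabel] = []
    for size in range(min_met, len(names) + 1):
        for combo in sorted(tuple(sorted(c)) for c in combinations(names, size)):
            labels.append(ScenarioLabel(combo))
    labels.append(NO_SEPSIS)
    return labels


def classify(result: CriteriaResult) -> ScenarioLabel:
    """Map a criteria evaluation to its exact-match scenario label."""
    if not result.sepsis_flag:
        return NO_SEPSIS
    return ScenarioLabel(tuple(sorted(result.met)))


def round_percentage(n_met: int, n_total: int) -> float:
    """100·n_met/n_total rounded half-up to two decimals (printed style)."""
    if n_total <= 0:
        raise ValueError("percentage undefined for non-positive denominator")
    pct = Decimal(100 * n_met) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScenarioPrevalenceTable:
    """Counts and fractions over every enumerated scenario plus no-sepsis."""

    set_name: str
    n_total: int
    rows: Mapping[ScenarioLabel, tuple[int, float]]

    def __post_init__(self) -> None:
        counts = sum(c for c, _ in self.rows.values())
        if counts != self.n_total:
            raise ValueError(f"scenario counts {counts} do not sum to n_total {self.n_total}")
        if abs(sum(f for _, f in self.rows.values()) - 1.0) > 1e-12:
            raise ValueError("scenario fractions do not sum to 1")

    def count(self, label: ScenarioLabel) -> int:
        return self.rows[label][0]

    def fraction(self, label: ScenarioLabel) -> float:
        return self.rows[label][1]

    def percentage(self, label: ScenarioLabel) -> float:
        return round_percentage(self.rows[label][0], self.n_total)

    def ranked(self) -> list[tuple[ScenarioLabel, int, float]]:
        """Rows sorted by count descending, label ascending as tie-break."""
        return sorted(
            ((lab, c, f) for lab, (c, f) in self.rows.items()),
            key=lambda t: (-t[1], t[0]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": [str(lab) for lab, _, _ in self.ranked()],
                "count": [c for _, c, _ in self.ranked()],
                "fraction": [f for _, _, f in self.ranked()],
            }
        )


def scenario_prevalence(
    observations: Sequence[AlignedObservation], cset: CriteriaSet
) -> ScenarioPrevalenceTable:
    """Classify each aligned observation once and tabulate scenario prevalence."""
    if not observations:
        raise ValueError("scenario prevalence undefined on an empty observation sequence")
    labels = enumerate_scenarios(cset.criterion_names, cset.min_met_for_sepsis)
    counts: dict[ScenarioLabel, int] = {lab: 0 for lab in labels}
    for obs in observations:
        lab = classify(evaluate(cset, obs))
        counts[lab] += 1
    n = len(observations)
    rows = {lab: (c, c / n) for lab, c in counts.items()}
    return ScenarioPrevalenceTable(set_name=cset.name, n_total=n, rows=rows)


@dataclass(frozen=True)
class PrevalenceResult:
    """Fraction of observations of one parameter meeting one criterion."""

    criterion: str
    n_met: int
    n_total: int

    @property
    def percentage(self) -> float:
        return round_percentage(self.n_met, self.n_total)


def criterion_prevalence(
    events: Iterable[ChartEvent], defn: CriterionDefinition
) -> PrevalenceResult:
    """Per-criterion prevalence over all events of the criterion's parameter."""
    n_met = 0
    n_total = 0
    for ev in events:
        if ev.parameter is not defn.parameter:
            continue
        n_total += 1
        if evaluate_criterion(defn, ev.value):
            n_met += 1
    if n_total == 0:
        raise ValueError(f"no events of parameter {defn.parameter.value} for {defn.name}")
    return PrevalenceResult(criterion=defn.name, n_met=n_met, n_total=n_total)
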