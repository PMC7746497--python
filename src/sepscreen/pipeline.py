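"""Four-way screening analysis: {qSOFA, SIRS} × {entire trajectory, first observation}.

The pipeline reads a long-format chart-event CSV, canonicalizes and
plausibility-filters it, and for each criteria set computes per-criterion
prevalence, aligned-scenario prevalence, summary statistics, pairwise
absolute Pearson correlations and kernel-density curves — once over every
record (entire trajectory) and once restricted to each admission's first
observations.  The result is a machine-readable JSON report plus CSV tables.

Phase-2 conventions: per-criterion prevalence and summary statistics use the
earliest event of each (admission, parameter); scenario and correlation
analyses use the earliest complete aligned snapshot per admission, which is
the only reading that keeps scenario classification well-defined.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from . import chartio
from .alignment import AlignedObservation, align, first_per_admission
from .chartio import (
    ChartEvent,
    DEFAULT_PLAUSIBILITY,
    Parameter,
    PlausibilityRanges,
    read_chart_events,
)
from .criteria import QSOFA, SIRS, CriteriaSet, criteria_set_from_dict
from .dichotomy import DEFAULT_BAND_EDGES, kde, pairwise_dichotomy, summary_stats
from .scenarios import criterion_prevalence, scenario_prevalence

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "load_pipeline_config",
    "validate_report",
    "REPORT_SCHEMA",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, overridable from a YAML/JSON file."""

    input_path: Path
    output_dir: Optional[Path] = None
    criteria_sets: tuple[CriteriaSet, ...] = (QSOFA, SIRS)
    plausibility: PlausibilityRanges = DEFAULT_PLAUSIBILITY
    tolerance_minutes: int = 0
    band_edges: tuple[float, float, float] = DEFAULT_BAND_EDGES
    kde_rule: str | float = "silverman"
    kde_grid_n: int = 512
    correlation_scope: str = "pairwise"  # phase 1: "pairwise" or "complete"
    strict_read: bool = True
    run_entire_trajectory: bool = True
    run_first_observation: bool = True
    export_densities: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "input_path": str(self.input_path),
            "criteria_sets": [c.to_dict() for c in self.criteria_sets],
            "plausibility": {p.value: list(r) for p, r in self.plausibility.ranges.items()},
            "tolerance_minutes": self.tolerance_minutes,
            "band_edges": list(self.band_edges),
            "kde_rule": self.kde_rule,
            "kde_grid_n": self.kde_grid_n,
            "correlation_scope": self.correlation_scope,
            "strict_read": self.strict_read,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML (or JSON) config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    if "input_path" in raw:
        kwargs["input_path"] = Path(raw["input_path"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])
    if "criteria_sets" in raw:
        kwargs["criteria_sets"] = tuple(criteria_set_from_dict(d) for d in raw["criteria_sets"])
    if "plausibility" in raw:
        kwargs["plausibility"] = DEFAULT_PLAUSIBILITY.with_overrides(
            {Parameter(p): tuple(v) for p, v in raw["plausibility"].items()}
        )
    for key in (
        "tolerance_minutes",
        "kde_rule",
        "kde_grid_n",
        "correlation_scope",
        "strict_read",
        "run_entire_trajectory",
        "run_first_observation",
        "export_densities",
        "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "band_edges" in raw:
        kwargs["band_edges"] = tuple(raw["band_edges"])
    kwargs.update(overrides)
    if "input_path" not in kwargs:
        raise PipelineError("config: input_path is required")
    return PipelineConfig(**kwargs)


def _phase_block(
    events: Sequence[ChartEvent],
    aligned: Sequence[AlignedObservation],
    cset: CriteriaSet,
    config: PipelineConfig,
    phase: str,
    export_dir: Optional[Path],
) -> dict:
    """All analyses of one (criteria set, phase) cell."""
    block: dict[str, Any] = {"n_events": len(events), "n_aligned": len(aligned)}

    prevalence = []
    for defn in cset.criteria:
        param_events = [e for e in events if e.parameter is defn.parameter]
        if param_events:
            res = criterion_prevalence(param_events, defn)
            prevalence.append(
                {
                    "criterion": res.criterion,
                    "parameter": defn.parameter.value,
                    "n_met": res.n_met,
                    "n_total": res.n_total,
                    "percentage": res.percentage,
                }
            )
        else:
            prevalence.append(
                {
                    "criterion": defn.name,
                    "parameter": defn.parameter.value,
                    "n_met": 0,
                    "n_total": 0,
                    "percentage": None,
                }
            )
    block["criterion_prevalence"] = prevalence

    if aligned:
        table = scenario_prevalence(list(aligned), cset)
        block["scenarios"] = {
            "n_total": table.n_total,
            "rows": [
                {
                    "scenario": str(lab),
                    "count": count,
                    "fraction": fraction,
                    "percentage": table.percentage(lab),
                }
                for lab, count, fraction in table.ranked()
            ],
        }
    else:
        block["scenarios"] = None

    stats_block: dict[str, Any] = {}
    for p in cset.parameters:
        vals = [e.value for e in events if e.parameter is p]
        stats_block[p.value] = summary_stats(vals).to_dict() if len(vals) >= 2 else None
    block["summary_stats"] = stats_block

    if phase == "entire_trajectory":
        corr = pairwise_dichotomy(
            list(events), cset.parameters, config.band_edges, config.correlation_scope
        )
    else:
        corr = (
            pairwise_dichotomy(list(aligned), cset.parameters, config.band_edges)
            if aligned
            else None
        )
    block["correlation"] = corr.to_dict() if corr is not None else None

    density_files: dict[str, str] = {}
    if config.export_densities and export_dir is not None:
        for defn in cset.criteria:
            vals = [e.value for e in events if e.parameter is defn.parameter]
            if len(vals) < 2:
                continue
            cutoffs = (
                defn.band if defn.band is not None else (defn.threshold,)
            )
            curve = kde(
                vals,
                bandwidth_rule=config.kde_rule,
                grid_n=config.kde_grid_n,
                cutoffs=cutoffs,
                parameter=defn.parameter,
            )
            name = f"density_{cset.name}_{phase}_{defn.parameter.value}.csv"
            path = export_dir / name
            with open(path, "w") as fh:
                fh.write("grid,density\n")
                for g, d in zip(curve.grid, curve.density):
                    fh.write(f"{g:.10g},{d:.10g}\n")
            density_files[defn.parameter.value] = name
    block["density_files"] = density_files
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full four-way analysis and return the report dict.

    Stage order: read → canonicalize (on read) → plausibility filter →
    phase subsetting → align → evaluate/classify → prevalence & dichotomy.
    Deterministic for a fixed input and configuration.
    """
    if not Path(config.input_path).exists():
        raise PipelineError(f"read: input path does not exist: {config.input_path}")
    export_dir = Path(config.output_dir) if config.output_dir is not None else None
    if export_dir is not None:
        export_dir.mkdir(parents=True, exist_ok=True)

    try:
        events = read_chart_events(config.input_path, strict=config.strict_read)
    except (chartio.ChartFormatError, OSError) as exc:
        raise PipelineError(f"read: {exc}") from exc

    kept, excluded = chartio.filter_plausible(events, config.plausibility)

    tolerance = timedelta(minutes=config.tolerance_minutes)
    analyses: dict[str, Any] = {}
    for cset in config.criteria_sets:
        set_events = [e for e in kept if e.parameter in cset.parameters]
        cell: dict[str, Any] = {}
        aligned = align(set_events, cset.parameters, tolerance) if set_events else []
        if config.run_entire_trajectory:
            cell["entire_trajectory"] = _phase_block(
                set_events, aligned, cset, config, "entire_trajectory", export_dir
            )
        if config.run_first_observation:
            first_events = first_per_admission(set_events, "per_parameter")
            first_aligned = first_per_admission(aligned, "first_aligned")
            cell["first_observation"] = _phase_block(
                first_events, first_aligned, cset, config, "first_observation", export_dir
            )
        analyses[cset.name] = cell

    from . import __version__

    report: dict[str, Any] = {
        "metadata": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "input_path": str(config.input_path),
        },
        "filtering": {
            "n_read": len(events),
            "n_excluded": len(excluded),
            "n_kept": len(kept),
            "exclusions_by_parameter": _exclusion_counts(excluded),
        },
        "analyses": analyses,
    }
    if report["filtering"]["n_read"] != report["filtering"]["n_kept"] + report["filtering"]["n_excluded"]:
        raise PipelineError("filter: ledger does not reconcile (read != kept + excluded)")
    validate_report(report)

    if export_dir is not None:
        (export_dir / "report.json").write_text(json.dumps(report, indent=2))
        for set_name, cell in analyses.items():
            for phase, block in cell.items():
                if block["scenarios"] is None:
                    continue
                path = export_dir / f"scenarios_{set_name}_{phase}.csv"
                with open(path, "w") as fh:
                    fh.write("scenario,count,fraction\n")
                    for row in block["scenarios"]["rows"]:
                        fh.write(f"{row['scenario']},{row['count']},{row['fraction']:.10g}\n")
    return report


def _exclusion_counts(excluded: Sequence[chartio.ExcludedEvent]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ex in excluded:
        key = ex.event.parameter.value
        counts[key] = counts.get(key, 0) + 1
    return counts


#: Minimal structural schema of the report (subset of JSON Schema).
REPORT_SCHEMA: Mapping[str, Any] = {
    "type": "object",
    "required": ["metadata", "filtering", "analyses"],
    "properties": {
        "metadata": {
            "type": "object",
            "required": ["package_version", "config_hash", "seed", "input_path"],
        },
        "filtering": {
            "type": "object",
            "required": ["n_read", "n_excluded", "n_kept"],
            "properties": {
                "n_read": {"type": "integer"},
                "n_excluded": {"type": "integer"},
                "n_kept": {"type": "integer"},
            },
        },
        "analyses": {
            "type": "object",
            "value_schema": {
                "type": "object",
                "value_schema": {
                    "type": "object",
                    "required": [
                        "n_events",
                        "n_aligned",
                        "criterion_prevalence",
                        "scenarios",
                        "summary_stats",
                        "correlation",
                        "density_files",
                    ],
                },
            },
        },
    },
}

_TYPES = {"object": dict, "integer": int, "number": (int, float), "string": str, "array": list}


def _check_schema(obj: Any, schema: Mapping[str, Any], path: str) -> None:
    expected = schema.get("type")
    if expected is not None and not isinstance(obj, _TYPES[expected]):
        raise ValueError(f"report schema violation at {path}: expected {expected}")
    if isinstance(obj, dict):
        for key in schema.get("required", ()):
            if key not in obj:
                raise ValueError(f"report schema violation at {path}: missing key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_schema(obj[key], sub, f"{path}.{key}")
        value_schema = schema.get("value_schema")
        if value_schema is not None:
            for key, val in obj.items():
                _check_schema(val, value_schema, f"{path}.{key}")


def validate_report(report: Mapping[str, Any]) -> None:
    """Raise ``ValueError`` if the report violates its published schema."""
    _check_schema(report, REPORT_SCHEMA, "report")
    filt = report["filtering"]
    if filt["n_read"] != filt["n_kept"] + filt["n_excluded"]:
        raise ValueError("report filtering ledger does not reconcile")
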