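"""Summary statistics, pairwise absolute Pearson correlation and KDE curves.

Multicollinearity among screening parameters would undermine their use as
joint predictors, so each unordered parameter pair is summarized by the
absolute Pearson coefficient |r| computed on simultaneous observations.  With
cohort sizes in the tens or hundreds of thousands even tiny coefficients are
"statistically significant", so the verdict is effect-size based: |r| is
banded as negligible [0, 0.1), weak [0.1, 0.3), moderate [0.3, 0.5) or
collinear [0.5, 1].  A p-value is reported for completeness but never drives
the band.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .alignment import AlignedObservation, align
from .chartio import ChartEvent, Parameter

__all__ = [
    "SummaryStats",
    "PairCorrelation",
    "CorrelationReport",
    "DensityCurve",
    "DegenerateInputError",
    "DEFAULT_BAND_EDGES",
    "summary_stats",
    "abs_pearson",
    "correlation_band",
    "pairwise_dichotomy",
    "kde",
]


class DegenerateInputError(ValueError):
    """Input has zero variance (or is otherwise too degenerate to use)."""


@dataclass(frozen=True)
class SummaryStats:
    """Mean (sample SD) and median (IQR) of one parameter's values."""

    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
        }


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Sample mean/SD (n−1 denominator) and linearly interpolated quartiles."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return SummaryStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )


def abs_pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Product-moment correlation of two paired sequences: (r, |r|, n)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("inputs must be paired 1-d sequences of equal length")
    if xa.size < 2:
        raise ValueError(f"need at least 2 pairs, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("zero variance input")
    r = float(stats.pearsonr(xa, ya).statistic)
    return r, abs(r), int(xa.size)


#: |r| band edges: [0, .1) negligible, [.1, .3) weak, [.3, .5) moderate, [.5, 1] collinear.
DEFAULT_BAND_EDGES: tuple[float, float, float] = (0.1, 0.3, 0.5)

_BAND_NAMES = ("negligible", "weak", "moderate", "collinear")


def correlation_band(
    abs_r: float, edges: tuple[float, float, float] = DEFAULT_BAND_EDGES
) -> str:
    """Monotone step function assigning an effect-size band to |r|."""
    if not 0.0 <= abs_r <= 1.0:
        raise ValueError(f"|r| must be in [0, 1], got {abs_r}")
    if tuple(sorted(edges)) != tuple(edges):
        raise ValueError(f"band edges must be increasing, got {edges}")
    for edge, name in zip(edges, _BAND_NAMES):
        if abs_r < edge:
            return name
    return _BAND_NAMES[-1]


@dataclass(frozen=True)
class PairCorrelation:
    """Correlation summary for one unordered parameter pair."""

    r: Optional[float]
    abs_r: Optional[float]
    n_pairs: int
    band: Optional[str]
    p_value: Optional[float] = None
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "abs_r": self.abs_r,
            "n_pairs": self.n_pairs,
            "band": self.band,
            "p_value": self.p_value,
            "error": self.error,
        }


@dataclass(frozen=True)
class CorrelationReport:
    """Per-pair correlation entries keyed by (parameter, parameter)."""

    pairs: Mapping[tuple[Parameter, Parameter], PairCorrelation]

    def __getitem__(self, pair: tuple[Parameter, Parameter]) -> PairCorrelation:
        a, b = Parameter(pair[0]), Parameter(pair[1])
        key = tuple(sorted((a, b), key=lambda p: p.value))
        return self.pairs[key]  # type: ignore[index]

    def to_dict(self) -> dict:
        return {
            f"{a.value}-{b.value}": pc.to_dict() for (a, b), pc in self.pairs.items()
        }


def _pair_values(
    records: Sequence[ChartEvent] | Sequence[AlignedObservation],
    a: Parameter,
    b: Parameter,
    scope: str,
    all_params: Sequence[Parameter],
) -> tuple[np.ndarray, np.ndarray]:
    if records and isinstance(records[0], AlignedObservation):
        xs = [obs.values[a] for obs in records]  # type: ignore[union-attr]
        ys = [obs.values[b] for obs in records]  # type: ignore[union-attr]
        return np.asarray(xs), np.asarray(ys)
    params = all_params if scope == "complete" else (a, b)
    obs = align(records, params)  # type: ignore[arg-type]
    return (
        np.asarray([o.values[a] for o in obs]),
        np.asarray([o.values[b] for o in obs]),
    )


def pairwise_dichotomy(
    records: Sequence[ChartEvent] | Sequence[AlignedObservation],
    parameters: Sequence[Parameter],
    band_edges: tuple[float, float, float] = DEFAULT_BAND_EDGES,
    scope: str = "pairwise",
) -> CorrelationReport:
    """Absolute Pearson correlation for every unordered parameter pair.

    Given raw chart events, each pair is aligned on the chart times where both
    parameters are present (``scope="pairwise"``) or on times where the full
    parameter set is present (``scope="complete"``).  Given aligned
    observations, their values are used directly.  A degenerate pair (zero
    variance or fewer than two simultaneous observations) is marked in its
    entry rather than aborting the report.
    """
    if scope not in ("pairwise", "complete"):
        raise ValueError(f"unknown correlation scope {scope!r}")
    params = [Parameter(p) for p in parameters]
    out: dict[tuple[Parameter, Parameter], PairCorrelation] = {}
    for a, b in itertools.combinations(sorted(params, key=lambda p: p.value), 2):
        x, y = _pair_values(records, a, b, scope, params)
        try:
            if x.size < 2:
                raise DegenerateInputError(f"only {x.size} simultaneous observation(s)")
            r, abs_r, n = abs_pearson(x, y)
            p = float(stats.pearsonr(x, y).pvalue)
            out[(a, b)] = PairCorrelation(
                r=r, abs_r=abs_r, n_pairs=n, band=correlation_band(abs_r, band_edges), p_value=p
            )
        except (DegenerateInputError, ValueError) as exc:
            out[(a, b)] = PairCorrelation(
                r=None, abs_r=None, n_pairs=int(x.size), band=None, error=str(exc)
            )
    return CorrelationReport(pairs=out)


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density estimate on an even grid, with cutoff annotations."""

    parameter: Optional[Parameter]
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    cutoffs: tuple[float, ...] = field(default_factory=tuple)

    def integral(self) -> float:
        """Trapezoid mass of the curve (≈1 when the grid spans the data)."""
        return float(np.trapezoid(self.density, self.grid))

    def at(self, x: float) -> float:
        """Linear interpolation of the density at ``x``."""
        return float(np.interp(x, self.grid, self.density))


def _bandwidth(x: np.ndarray, rule: str | float) -> float:
    if isinstance(rule, (int, float)):
        if rule <= 0:
            raise ValueError("fixed bandwidth must be positive")
        return float(rule)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance: rule-based bandwidth undefined")
    n = x.size
    if rule == "scott":
        return 1.06 * sd * n ** (-1 / 5)
    if rule == "silverman":
        q25, q75 = np.quantile(x, [0.25, 0.75])
        iqr = float(q75 - q25)
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * n ** (-1 / 5)
    raise ValueError(f"unknown bandwidth rule {rule!r}")


def kde(
    values: Sequence[float],
    bandwidth_rule: str | float = "silverman",
    grid_n: int = 512,
    cutoffs: Iterable[float] = (),
    parameter: Optional[Parameter] = None,
) -> DensityCurve:
    """Gaussian-kernel density on an even grid spanning the data ± 4 bandwidths.

    ``bandwidth_rule`` is ``"silverman"`` (0.9·min(sd, IQR/1.34)·n^(−1/5)),
    ``"scott"`` (1.06·sd·n^(−1/5)) or a fixed positive bandwidth.  Criterion
    thresholds relevant to the parameter can be attached as annotations.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if grid_n < 16:
        raise ValueError(f"grid_n must be at least 16, got {grid_n}")
    h = _bandwidth(x, bandwidth_rule)
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, int(grid_n))
    # evaluate in grid chunks to bound the (grid × data) kernel matrix
    dens = np.empty_like(grid)
    norm = 1.0 / (x.size * h * math.sqrt(2 * math.pi))
    step = max(1, int(4_000_000 // max(x.size, 1)))
    for i in range(0, grid.size, step):
        z = (grid[i : i + step, None] - x[None, :]) / h
        dens[i : i + step] = np.exp(-0.5 * z * z).sum(axis=1) * norm
    return DensityCurve(
        parameter=parameter,
        grid=grid,
        density=dens,
        bandwidth=h,
        cutoffs=tuple(float(c) for c in cutoffs),
    )
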