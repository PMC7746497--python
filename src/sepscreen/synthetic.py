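"""Synthetic ICU chart-event cohorts with a Gaussian copula.

The generator emulates the structure of long-format ICU charting: per
admission, each of the six screening parameters is observed on its own
sampling grid (vitals roughly hourly, GCS and temperature every few hours,
white cell counts with lab draws every half day), values follow configurable
marginal distributions, and simultaneous values are coupled through a latent
multivariate normal with a configurable correlation matrix (a Gaussian
copula).  Only the marginal moments and pairwise correlations of the real
cohort are emulated — there are no physiological time dynamics.

A second generator plants known scenario labels: it draws a label per
observation and samples each parameter from its marginal truncated to the
met or safe side of the corresponding criterion, so the planted label is
recovered by classification with probability one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .alignment import AlignedObservation
from .chartio import CANONICAL_UNITS, ChartEvent, Parameter
from .criteria import Comparison, CriteriaSet, CriterionDefinition, evaluate_criterion
from .scenarios import NO_SEPSIS, ScenarioLabel, enumerate_scenarios

__all__ = [
    "ConfigError",
    "MarginalSpec",
    "CohortConfig",
    "CohortResult",
    "ScenarioMixConfig",
    "DEFAULT_MARGINALS",
    "DEFAULT_LATENT_CORRELATION",
    "DEFAULT_SAMPLING_INTERVALS",
    "PARAM_ORDER",
    "repair_correlation",
    "generate_cohort",
    "generate_scenario_mix",
]


class ConfigError(ValueError):
    """A generator configuration is internally inconsistent."""


_U_EPS = 1e-12  # clip copula uniforms away from 0/1 before inverse CDFs


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal law of one parameter, truncated to its plausible range.

    ``family`` is ``"normal"``, ``"lognormal"`` (moment-matched to
    mean/sd) or ``"discrete_quantile"`` (a normal binned to the integers of
    ``bounds``, used for the Glasgow Coma Scale).
    """

    parameter: Parameter
    family: str
    mean: float
    sd: float
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "discrete_quantile"):
            raise ConfigError(f"unknown marginal family {self.family!r}")
        if self.sd <= 0:
            raise ConfigError(f"{self.parameter}: sd must be positive")
        lo, hi = self.bounds
        if not lo < hi:
            raise ConfigError(f"{self.parameter}: bounds must be ordered, got {self.bounds}")
        if self.family == "lognormal" and self.mean <= 0:
            raise ConfigError(f"{self.parameter}: lognormal mean must be positive")

    def _dist(self):
        """Underlying (untruncated) continuous distribution."""
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
        return stats.norm(loc=self.mean, scale=self.sd)

    def _support(self) -> tuple[float, float]:
        """Continuous truncation interval (half-integer widened when discrete)."""
        lo, hi = self.bounds
        if self.family == "discrete_quantile":
            return lo - 0.5, hi + 0.5
        return lo, hi

    def mass(self, a: float, b: float) -> float:
        """Probability mass of the untruncated law on [a, b] ∩ support."""
        s_lo, s_hi = self._support()
        a, b = max(a, s_lo), min(b, s_hi)
        if a >= b:
            return 0.0
        cdf = self._dist().cdf
        return float(cdf(b) - cdf(a))

    def ppf_in(self, u: np.ndarray, region: Optional[tuple[float, float]] = None) -> np.ndarray:
        """Inverse CDF of the marginal truncated to ``region`` (default: support)."""
        dist = self._dist()
        a, b = self._support()
        if region is not None:
            a, b = max(a, region[0]), min(b, region[1])
        pa, pb = float(dist.cdf(a)), float(dist.cdf(b))
        if pb - pa <= 0:
            raise ConfigError(f"{self.parameter}: empty truncation region [{a}, {b}]")
        u = np.clip(np.asarray(u, dtype=float), _U_EPS, 1.0 - _U_EPS)
        x = dist.ppf(pa + u * (pb - pa))
        x = np.clip(x, a, b)
        if self.family == "discrete_quantile":
            lo, hi = self.bounds
            x = np.clip(np.rint(x), lo, hi)
        return x

    def integer_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, weights) of the binned integer law; discrete family only."""
        if self.family != "discrete_quantile":
            raise ConfigError(f"{self.parameter}: not a discrete marginal")
        lo, hi = int(self.bounds[0]), int(self.bounds[1])
        ks = np.arange(lo, hi + 1)
        cdf = self._dist().cdf
        upper = np.minimum(ks + 0.5, hi + 0.5)
        lower = np.maximum(ks - 0.5, lo - 0.5)
        w = cdf(upper) - cdf(lower)
        return ks.astype(float), np.asarray(w, dtype=float)

    def expected_mean(self) -> float:
        """Analytic mean of the truncated (and binned, if discrete) marginal."""
        if self.family == "discrete_quantile":
            ks, w = self.integer_pmf()
            return float(np.sum(ks * w) / np.sum(w))
        dist = self._dist()
        a, b = self._support()
        mass = dist.cdf(b) - dist.cdf(a)
        return float(dist.expect(lb=a, ub=b) / mass)


#: Marginal defaults: entire-trajectory cohort moments of each parameter.
DEFAULT_MARGINALS: Mapping[Parameter, MarginalSpec] = {
    Parameter.SABP: MarginalSpec(Parameter.SABP, "normal", 116.4, 24.78, (20.0, 300.0)),
    Parameter.GCS: MarginalSpec(Parameter.GCS, "discrete_quantile", 11.17, 3.66, (3.0, 15.0)),
    Parameter.RR: MarginalSpec(Parameter.RR, "normal", 21.07, 6.52, (0.0, 80.0)),
    Parameter.HR: MarginalSpec(Parameter.HR, "normal", 89.1, 18.61, (0.0, 300.0)),
    Parameter.BT: MarginalSpec(Parameter.BT, "normal", 98.37, 1.57, (77.0, 110.0)),
    Parameter.WBC: MarginalSpec(Parameter.WBC, "lognormal", 13.14, 7.30, (0.0, 200.0)),
}

#: Latent pairwise correlations (weak throughout; strongest HR–RR and HR–BT).
DEFAULT_LATENT_CORRELATION: Mapping[frozenset, float] = {
    frozenset({Parameter.HR, Parameter.RR}): 0.32,
    frozenset({Parameter.HR, Parameter.BT}): 0.34,
    frozenset({Parameter.HR, Parameter.WBC}): 0.13,
    frozenset({Parameter.RR, Parameter.BT}): 0.11,
    frozenset({Parameter.RR, Parameter.WBC}): 0.05,
    frozenset({Parameter.BT, Parameter.WBC}): 0.03,
    frozenset({Parameter.RR, Parameter.GCS}): 0.09,
    frozenset({Parameter.GCS, Parameter.SABP}): 0.07,
    frozenset({Parameter.RR, Parameter.SABP}): 0.04,
}

#: Charting cadence in hours: vitals hourly, GCS/BT 4-hourly, labs 12-hourly.
DEFAULT_SAMPLING_INTERVALS: Mapping[Parameter, int] = {
    Parameter.SABP: 1,
    Parameter.RR: 1,
    Parameter.HR: 1,
    Parameter.GCS: 4,
    Parameter.BT: 4,
    Parameter.WBC: 12,
}

PARAM_ORDER: tuple[Parameter, ...] = (
    Parameter.SABP,
    Parameter.GCS,
    Parameter.RR,
    Parameter.HR,
    Parameter.BT,
    Parameter.WBC,
)


def repair_correlation(matrix: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Return the nearest-by-eigenvalue-clipping valid correlation matrix.

    Negative eigenvalues are clipped to a small positive floor and the result
    rescaled to unit diagonal.  If the repair moves any entry by more than
    ``tol`` the matrix is considered irreparably non-PSD.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ConfigError("correlation matrix must have unit diagonal")
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= 1e-10:
        return m
    clipped = np.clip(vals, 1e-8, None)
    repaired = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    if np.max(np.abs(repaired - m)) > tol:
        raise ConfigError("correlation matrix is not positive semi-definite within repair tolerance")
    return repaired


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_admissions: int = 200
    stay_hours_median: float = 48.0
    stay_hours_log_sd: float = 0.6
    max_stay_hours: float = 21 * 24.0
    sampling_interval_hours: Mapping[Parameter, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_INTERVALS)
    )
    marginals: Mapping[Parameter, MarginalSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    latent_correlation: Mapping[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_CORRELATION)
    )
    outlier_rate: float = 0.0
    mortality_probability: float = 0.2111
    seed: int = 0
    admit_base: datetime = datetime(2019, 1, 1)

    def __post_init__(self) -> None:
        if self.n_admissions < 0:
            raise ConfigError("n_admissions must be non-negative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must be a probability")
        if not 0.0 <= self.mortality_probability <= 1.0:
            raise ConfigError("mortality_probability must be a probability")
        if self.stay_hours_median <= 0 or self.stay_hours_log_sd < 0:
            raise ConfigError("stay-length parameters must be positive")
        for p in PARAM_ORDER:
            if p not in self.marginals:
                raise ConfigError(f"marginal missing for {p.value}")
            if self.sampling_interval_hours.get(p, 0) < 1:
                raise ConfigError(f"sampling interval for {p.value} must be >= 1 hour")

    def correlation_matrix(self) -> np.ndarray:
        """Assemble (and if needed repair) the latent correlation matrix."""
        k = len(PARAM_ORDER)
        m = np.eye(k)
        for pair, r in self.latent_correlation.items():
            a, b = sorted(pair, key=lambda p: PARAM_ORDER.index(p))
            if not -1.0 < float(r) < 1.0:
                raise ConfigError(f"latent correlation for {a}-{b} out of (-1, 1): {r}")
            i, j = PARAM_ORDER.index(a), PARAM_ORDER.index(b)
            m[i, j] = m[j, i] = float(r)
        return repair_correlation(m)


@dataclass(frozen=True)
class CohortResult:
    """A generated cohort: events plus per-admission mortality labels."""

    events: list[ChartEvent]
    mortality: Mapping[str, bool]
    n_outliers_injected: int
    seed: int

    @property
    def mortality_rate(self) -> float:
        if not self.mortality:
            return float("nan")
        return sum(self.mortality.values()) / len(self.mortality)


def _inject_outliers(
    rng: np.random.Generator, values: np.ndarray, spec: MarginalSpec, rate: float
) -> tuple[np.ndarray, int]:
    """Replace a random subset of values with ones strictly outside bounds."""
    if rate <= 0 or values.size == 0:
        return values, 0
    mask = rng.random(values.size) < rate
    k = int(mask.sum())
    if k == 0:
        return values, 0
    lo, hi = spec.bounds
    above = rng.random(k) < 0.5
    out = np.where(
        above,
        hi + 1.0 + rng.exponential(scale=0.1 * abs(hi) + 1.0, size=k),
        lo - 1.0 - rng.exponential(scale=0.1 * abs(lo) + 1.0, size=k),
    )
    values = values.copy()
    values[mask] = out
    return values, k


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate a synthetic chart-event cohort; fully determined by the seed.

    Per admission a lognormal stay length is drawn, a latent multivariate
    normal series is sampled on an hourly grid, and each parameter observes
    the latent series on its own interval grid through its marginal's inverse
    CDF.  Simultaneous observations therefore carry the configured latent
    correlation.  Outliers are injected strictly outside the marginal bounds
    at the configured rate, and each admission receives an independent
    Bernoulli mortality label.
    """
    rng = np.random.default_rng(config.seed)
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(PARAM_ORDER)))
    events: list[ChartEvent] = []
    mortality: dict[str, bool] = {}
    n_outliers = 0
    width = max(5, len(str(max(config.n_admissions, 1))))
    for i in range(config.n_admissions):
        adm = f"ADM{i + 1:0{width}d}"
        stay = math.exp(
            math.log(config.stay_hours_median)
            + config.stay_hours_log_sd * rng.standard_normal()
        )
        hours = int(min(stay, config.max_stay_hours)) + 1
        latent = rng.standard_normal((hours, len(PARAM_ORDER))) @ chol.T
        admit = config.admit_base + timedelta(
            days=int(i % 366), minutes=int(rng.integers(0, 1440))
        )
        for j, p in enumerate(PARAM_ORDER):
            grid = np.arange(0, hours, config.sampling_interval_hours[p])
            u = stats.norm.cdf(latent[grid, j])
            vals = config.marginals[p].ppf_in(u)
            vals, k = _inject_outliers(rng, vals, config.marginals[p], config.outlier_rate)
            n_outliers += k
            unit = CANONICAL_UNITS[p]
            for t, v in zip(grid, vals):
                events.append(
                    ChartEvent(
                        admission_id=adm,
                        chart_time=admit + timedelta(hours=int(t)),
                        parameter=p,
                        value=float(v),
                        source_unit=unit,
                    )
                )
        mortality[adm] = bool(rng.random() < config.mortality_probability)
    return CohortResult(
        events=events, mortality=mortality, n_outliers_injected=n_outliers, seed=config.seed
    )


@dataclass(frozen=True)
class ScenarioMixConfig:
    """A planted mixture over scenario labels for one criteria set."""

    mix: Mapping[ScenarioLabel, float]
    n_observations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observations < 0:
            raise ConfigError("n_observations must be non-negative")
        probs = list(self.mix.values())
        if any(p < 0 for p in probs):
            raise ConfigError("mixture probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"mixture probabilities sum to {sum(probs)}, expected 1")


def _criterion_regions(
    spec: MarginalSpec, defn: CriterionDefinition, met: bool
) -> list[tuple[float, float]]:
    """Continuous truncation interval(s) for the met or safe side of a criterion."""
    lo, hi = spec._support()
    c, th = defn.comparison, defn.threshold
    eps = 1e-6 * max(1.0, abs(th) if th is not None else 1.0)
    if c is Comparison.AT_LEAST:
        return [(th, hi)] if met else [(lo, th - eps)]
    if c is Comparison.AT_MOST:
        return [(lo, th)] if met else [(th + eps, hi)]
    if c is Comparison.GREATER:
        return [(th + eps, hi)] if met else [(lo, th)]
    if c is Comparison.LESS:
        return [(lo, th - eps)] if met else [(th, hi)]
    a, b = defn.band  # type: ignore[misc]
    eps = 1e-6 * max(1.0, abs(a), abs(b))
    if met:
        return [(lo, a - eps), (b + eps, hi)]
    return [(a, b)]


def _sample_side(
    rng: np.random.Generator,
    spec: MarginalSpec,
    defn: CriterionDefinition,
    met: bool,
    size: int,
) -> np.ndarray:
    """Sample the marginal restricted to the met/safe side of one criterion."""
    if spec.family == "discrete_quantile":
        ks, w = spec.integer_pmf()
        side = np.array([evaluate_criterion(defn, float(k)) == met for k in ks])
        w = w * side
        if w.sum() <= 0:
            raise ConfigError(
                f"{defn.name}: empty {'met' if met else 'safe'} region for {spec.parameter.value}"
            )
        return rng.choice(ks, size=size, p=w / w.sum())
    regions = _criterion_regions(spec, defn, met)
    masses = np.array([spec.mass(a, b) for a, b in regions])
    if masses.sum() <= 1e-15:
        raise ConfigError(
            f"{defn.name}: empty {'met' if met else 'safe'} region for {spec.parameter.value}"
        )
    out = np.empty(size)
    if len(regions) == 1:
        out[:] = spec.ppf_in(rng.random(size), regions[0])
        return out
    pick_first = rng.random(size) < masses[0] / masses.sum()
    u = rng.random(size)
    if pick_first.any():
        out[pick_first] = spec.ppf_in(u[pick_first], regions[0])
    if (~pick_first).any():
        out[~pick_first] = spec.ppf_in(u[~pick_first], regions[1])
    return out


def generate_scenario_mix(
    config: ScenarioMixConfig,
    cset: CriteriaSet,
    marginals: Mapping[Parameter, MarginalSpec] = DEFAULT_MARGINALS,
    base_time: datetime = datetime(2019, 1, 1),
) -> list[AlignedObservation]:
    """Generate aligned observations whose scenario labels are planted.

    Each observation draws a label from the mixture; every parameter is then
    sampled from its marginal truncated to the met side (its criterion is in
    the label) or the safe side (it is not), so classification recovers the
    planted label with probability one.
    """
    valid = set(enumerate_scenarios(cset.criterion_names, cset.min_met_for_sepsis))
    labels = list(config.mix.keys())
    for lab in labels:
        if lab not in valid:
            raise ConfigError(f"label {lab} is not a valid scenario of {cset.name}")
    for defn in cset.criteria:
        if defn.parameter not in marginals:
            raise ConfigError(f"marginal missing for {defn.parameter.value}")
    rng = np.random.default_rng(config.seed)
    n = config.n_observations
    probs = np.array([config.mix[lab] for lab in labels], dtype=float)
    draws = rng.choice(len(labels), size=n, p=probs / probs.sum())
    values = {defn.parameter: np.empty(n) for defn in cset.criteria}
    for li, lab in enumerate(labels):
        idx = np.where(draws == li)[0]
        if idx.size == 0:
            continue
        for defn in cset.criteria:
            met = defn.name in lab.criteria
            values[defn.parameter][idx] = _sample_side(
                rng, marginals[defn.parameter], defn, met, idx.size
            )
    out: list[AlignedObservation] = []
    for i in range(n):
        out.append(
            AlignedObservation(
                admission_id=f"SIM{i + 1:06d}",
                chart_time=base_time + timedelta(minutes=i),
                values={p: float(v[i]) for p, v in values.items()},
            )
        )
    return out
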