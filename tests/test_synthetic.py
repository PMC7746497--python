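"""Synthetic cohort generator: determinism, marginals, copula correlation,
outlier injection and planted scenario mixtures."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sepscreen.alignment import align
from sepscreen.chartio import DEFAULT_PLAUSIBILITY, Parameter, filter_plausible
from sepscreen.criteria import QSOFA, SIRS, evaluate
from sepscreen.dichotomy import abs_pearson
from sepscreen.scenarios import NO_SEPSIS, ScenarioLabel, classify, scenario_prevalence
from sepscreen.synthetic import (
    DEFAULT_MARGINALS,
    CohortConfig,
    ConfigError,
    MarginalSpec,
    ScenarioMixConfig,
    generate_cohort,
    generate_scenario_mix,
    repair_correlation,
)

AMS_RR = ScenarioLabel(("altered_mental_status", "high_respiratory_rate"))


class TestCohortBasics:
    def test_zero_admissions_empty(self):
        res = generate_cohort(CohortConfig(n_admissions=0, seed=1))
        assert res.events == [] and res.mortality == {}

    def test_seed_determinism_byte_identical(self, tmp_path):
        from sepscreen.chartio import write_chart_events

        cfg = CohortConfig(n_admissions=15, outlier_rate=0.01, seed=99)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.events == b.events
        assert a.mortality == b.mortality and a.n_outliers_injected == b.n_outliers_injected
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_chart_events(a.events, pa)
        write_chart_events(b.events, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_admissions=5, seed=1))
        b = generate_cohort(CohortConfig(n_admissions=5, seed=2))
        assert a.events != b.events

    def test_sampling_cadence_respected(self):
        res = generate_cohort(CohortConfig(n_admissions=3, seed=4))
        per_param = {p: [] for p in Parameter}
        for e in res.events:
            per_param[e.parameter].append((e.admission_id, e.chart_time))
        # WBC observed 12-hourly: far sparser than hourly RR
        assert len(per_param[Parameter.WBC]) < len(per_param[Parameter.RR]) / 4
        for adm, t in per_param[Parameter.WBC]:
            first = min(u for a2, u in per_param[Parameter.WBC] if a2 == adm)
            assert (t - first).total_seconds() % (12 * 3600) == 0

    def test_mortality_labels_one_per_admission(self):
        res = generate_cohort(CohortConfig(n_admissions=25, seed=6))
        assert set(res.mortality) == {e.admission_id for e in res.events}
        assert all(isinstance(v, bool) for v in res.mortality.values())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_admissions=-1)
        with pytest.raises(ConfigError):
            CohortConfig(outlier_rate=1.5)
        with pytest.raises(ConfigError):
            MarginalSpec(Parameter.HR, "normal", 80.0, -1.0, (0.0, 300.0))


class TestMarginalsAndCorrelation:
    def test_marginal_recovery_at_large_n(self):
        """Empirical means match the analytic truncated-marginal means (3 SE)."""
        cfg = CohortConfig(n_admissions=600, stay_hours_median=72,
                           stay_hours_log_sd=0.3, seed=13)
        res = generate_cohort(cfg)
        values = {p: [] for p in Parameter}
        for e in res.events:
            values[e.parameter].append(e.value)
        for p, spec in DEFAULT_MARGINALS.items():
            x = np.asarray(values[p])
            assert x.size >= 3000
            se = x.std(ddof=1) / math.sqrt(x.size)
            assert abs(x.mean() - spec.expected_mean()) < 3 * se, p
            lo, hi = spec.bounds
            assert x.min() >= lo and x.max() <= hi

    def test_truncation_barely_shifts_mild_marginals(self):
        # for all parameters except the hard-truncated GCS the analytic
        # truncated mean stays within 1% of the configured mean
        for p, spec in DEFAULT_MARGINALS.items():
            if p is Parameter.GCS:
                continue
            assert spec.expected_mean() == pytest.approx(spec.mean, rel=0.01), p

    def test_identity_correlation_gives_uncorrelated_pairs(self):
        cfg = CohortConfig(
            n_admissions=700, stay_hours_median=72, stay_hours_log_sd=0.3,
            latent_correlation={}, seed=17,
        )
        res = generate_cohort(cfg)
        aligned = align(res.events, (Parameter.HR, Parameter.RR))
        assert len(aligned) >= 50_000
        x = [o.values[Parameter.HR] for o in aligned]
        y = [o.values[Parameter.RR] for o in aligned]
        _, abs_r, _ = abs_pearson(x, y)
        assert abs_r < 0.03

    def test_gcs_values_are_integers_in_clinical_range(self):
        res = generate_cohort(CohortConfig(n_admissions=20, seed=21))
        gcs = [e.value for e in res.events if e.parameter is Parameter.GCS]
        assert gcs and all(v == int(v) and 3 <= v <= 15 for v in gcs)

    def test_non_psd_matrix_rejected_mild_indefiniteness_repaired(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ConfigError, match="positive semi-definite"):
            repair_correlation(bad)
        mild = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, -0.02], [0.7, -0.02, 1.0]])
        repaired = repair_correlation(mild)
        assert np.linalg.eigvalsh(repaired).min() >= -1e-10
        assert np.allclose(np.diag(repaired), 1.0)


class TestOutliers:
    def test_injected_outliers_all_removed_and_counted(self):
        cfg = CohortConfig(n_admissions=60, outlier_rate=0.02, seed=31)
        res = generate_cohort(cfg)
        assert res.n_outliers_injected > 0
        kept, excluded = filter_plausible(res.events, DEFAULT_PLAUSIBILITY)
        assert len(excluded) == res.n_outliers_injected
        assert len(kept) + len(excluded) == len(res.events)

    def test_zero_rate_injects_nothing(self):
        res = generate_cohort(CohortConfig(n_admissions=30, outlier_rate=0.0, seed=32))
        _, excluded = filter_plausible(res.events)
        assert res.n_outliers_injected == 0 and excluded == []


class TestScenarioMix:
    def test_pure_label_mix_classifies_to_plan(self):
        cfg = ScenarioMixConfig(mix={AMS_RR: 1.0}, n_observations=10, seed=41)
        obs = generate_scenario_mix(cfg, QSOFA)
        assert len(obs) == 10
        assert all(classify(evaluate(QSOFA, o)) == AMS_RR for o in obs)

    def test_pure_no_sepsis_scores_below_two(self):
        cfg = ScenarioMixConfig(mix={NO_SEPSIS: 1.0}, n_observations=10, seed=42)
        obs = generate_scenario_mix(cfg, QSOFA)
        assert all(evaluate(QSOFA, o).score <= 1 for o in obs)

    def test_mixture_fraction_recovered_within_binomial_bound(self):
        n = 20_000
        cfg = ScenarioMixConfig(mix={AMS_RR: 0.3, NO_SEPSIS: 0.7}, n_observations=n, seed=43)
        obs = generate_scenario_mix(cfg, QSOFA)
        frac = sum(classify(evaluate(QSOFA, o)) == AMS_RR for o in obs) / n
        assert abs(frac - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_sirs_mix_with_band_criteria(self):
        quad = ScenarioLabel(tuple(sorted(SIRS.criterion_names)))
        wbc_rr = ScenarioLabel(("abnormal_wbc", "tachypnea"))
        cfg = ScenarioMixConfig(
            mix={quad: 0.25, wbc_rr: 0.25, NO_SEPSIS: 0.5}, n_observations=400, seed=44
        )
        obs = generate_scenario_mix(cfg, SIRS)
        labels = [classify(evaluate(SIRS, o)) for o in obs]
        assert set(labels) == {quad, wbc_rr, NO_SEPSIS}

    def test_invalid_mixtures_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            ScenarioMixConfig(mix={AMS_RR: 0.4, NO_SEPSIS: 0.4}, n_observations=5)
        bogus = ScenarioLabel(("altered_mental_status",))  # below min_met
        cfg = ScenarioMixConfig(mix={bogus: 1.0}, n_observations=5)
        with pytest.raises(ConfigError, match="not a valid scenario"):
            generate_scenario_mix(cfg, QSOFA)

    def test_empty_truncation_region_rejected(self):
        # a safe-side RR restricted to an impossible interval
        tight = dict(DEFAULT_MARGINALS)
        tight[Parameter.RR] = MarginalSpec(Parameter.RR, "normal", 21.0, 6.5, (30.0, 80.0))
        cfg = ScenarioMixConfig(mix={NO_SEPSIS: 1.0}, n_observations=5, seed=45)
        with pytest.raises(ConfigError, match="empty"):
            generate_scenario_mix(cfg, QSOFA, marginals=tight)

    def test_prevalence_table_recovers_planted_mixture(self):
        pair = ScenarioLabel(tuple(sorted(("hypotension", "high_respiratory_rate"))))
        mix = {AMS_RR: 0.2, pair: 0.3, NO_SEPSIS: 0.5}
        cfg = ScenarioMixConfig(mix=mix, n_observations=5000, seed=46)
        obs = generate_scenario_mix(cfg, QSOFA)
        table = scenario_prevalence(obs, QSOFA)
        for lab, p in mix.items():
            se = math.sqrt(p * (1 - p) / 5000)
            assert abs(table.fraction(lab) - p) < 3 * se, lab
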