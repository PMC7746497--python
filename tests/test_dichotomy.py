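"""Summary statistics, absolute Pearson correlation and KDE curves."""

from __future__ import annotations

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepscreen.alignment import AlignedObservation
from sepscreen.chartio import ChartEvent, Parameter
from sepscreen.dichotomy import (
    DEFAULT_BAND_EDGES,
    DegenerateInputError,
    abs_pearson,
    correlation_band,
    kde,
    pairwise_dichotomy,
    summary_stats,
)


def pearson_from_definition(x, y):
    """Independent oracle: textbook product-moment formula, no library call."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestSummaryStats:
    def test_closed_form_small_sample(self):
        s = summary_stats([1.0, 2.0, 3.0])
        assert s.mean == 2.0 and s.sd == pytest.approx(1.0) and s.median == 2.0

    def test_constant_sample_has_zero_sd_degenerate_iqr(self):
        s = summary_stats([5.0] * 4)
        assert s.sd == 0.0 and (s.q25, s.q75) == (5.0, 5.0)

    def test_matches_direct_computation_on_seeded_draws(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100)
        s = summary_stats(x)
        assert s.mean == pytest.approx(float(np.mean(x)), abs=1e-12)
        assert s.sd == pytest.approx(float(np.std(x, ddof=1)), abs=1e-12)
        assert s.q25 <= s.median <= s.q75

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summary_stats([1.0])


class TestAbsPearson:
    def test_perfect_positive_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, abs_r, n = abs_pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0) and abs_r == pytest.approx(1.0) and n == 4

    def test_perfect_negative_linear_relation(self):
        x = [1.0, 2.0, 3.0]
        r, abs_r, _ = abs_pearson(x, [-v for v in x])
        assert r == pytest.approx(-1.0) and abs_r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            abs_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_large_samples_nearly_uncorrelated(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100_000)
        y = rng.standard_normal(100_000)
        _, abs_r, _ = abs_pearson(x, y)
        assert abs_r < 0.02  # ~ 3 / sqrt(n) sampling bound

    def test_matches_from_definition_oracle_on_50_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 21))
            x = rng.normal(size=n) * rng.uniform(0.5, 10)
            y = rng.normal(size=n) + rng.uniform(-0.5, 0.5) * x
            r, abs_r, _ = abs_pearson(x, y)
            expected = pearson_from_definition(list(x), list(y))
            assert r == pytest.approx(expected, abs=1e-12)
            assert abs_r == pytest.approx(abs(expected), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
        negate=st.booleans(),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b, negate):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 0.5 * x
        r_xy, abs_xy, _ = abs_pearson(x, y)
        r_yx, abs_yx, _ = abs_pearson(y, x)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        scale = -a if negate else a
        r_s, abs_s, _ = abs_pearson(scale * x + b, y)
        assert abs_s == pytest.approx(abs_xy, abs=1e-9)
        assert math.copysign(1, r_s) == math.copysign(1, r_xy) * math.copysign(1, scale)


class TestBanding:
    @pytest.mark.parametrize(
        "abs_r,expected",
        [
            (0.0, "negligible"),
            (0.04, "negligible"),
            (0.09999, "negligible"),
            (0.1, "weak"),
            (0.29, "weak"),
            (0.3, "moderate"),
            (0.34, "moderate"),
            (0.49, "moderate"),
            (0.5, "collinear"),
            (1.0, "collinear"),
        ],
    )
    def test_band_assignment(self, abs_r, expected):
        assert correlation_band(abs_r) == expected

    def test_band_is_monotone_step_function(self):
        order = ["negligible", "weak", "moderate", "collinear"]
        grid = np.linspace(0, 1, 201)
        ranks = [order.index(correlation_band(v)) for v in grid]
        assert ranks == sorted(ranks)


class TestPairwiseDichotomy:
    def _aligned(self, xy_pairs):
        t0 = datetime(2021, 1, 1)
        return [
            AlignedObservation(
                "A1", t0 + timedelta(minutes=i), {Parameter.HR: x, Parameter.RR: y}
            )
            for i, (x, y) in enumerate(xy_pairs)
        ]

    def test_entry_per_unordered_pair_with_band(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(80, 10, 200), rng.normal(20, 4, 200)))
        report = pairwise_dichotomy(self._aligned(pairs), (Parameter.HR, Parameter.RR))
        entry = report[(Parameter.RR, Parameter.HR)]  # order-insensitive lookup
        assert entry.n_pairs == 200 and entry.band is not None
        assert entry.abs_r == pytest.approx(abs(entry.r))

    def test_degenerate_pair_marked_not_fatal(self):
        pairs = [(80.0, 20.0), (80.0, 25.0), (80.0, 30.0)]
        report = pairwise_dichotomy(self._aligned(pairs), (Parameter.HR, Parameter.RR))
        entry = report[(Parameter.HR, Parameter.RR)]
        assert entry.r is None and entry.error is not None

    def test_pairwise_scope_uses_pair_complete_chart_times(self):
        t0 = datetime(2021, 1, 1)
        events = []
        rng = np.random.default_rng(5)
        for i in range(50):  # HR+RR at every hour, BT only on even hours
            t = t0 + timedelta(hours=i)
            events.append(ChartEvent("A1", t, Parameter.HR, float(rng.normal(80, 9))))
            events.append(ChartEvent("A1", t, Parameter.RR, float(rng.normal(20, 3))))
            if i % 2 == 0:
                events.append(ChartEvent("A1", t, Parameter.BT, float(rng.normal(98, 1))))
        params = (Parameter.HR, Parameter.RR, Parameter.BT)
        pairwise = pairwise_dichotomy(events, params, scope="pairwise")
        complete = pairwise_dichotomy(events, params, scope="complete")
        assert pairwise[(Parameter.HR, Parameter.RR)].n_pairs == 50
        assert complete[(Parameter.HR, Parameter.RR)].n_pairs == 25
        assert pairwise[(Parameter.BT, Parameter.HR)].n_pairs == 25


class TestKde:
    def test_symmetric_sample_gives_symmetric_density(self):
        curve = kde([-1.0, 1.0], bandwidth_rule=0.5)
        left = np.interp(-0.7, curve.grid, curve.density)
        right = np.interp(0.7, curve.grid, curve.density)
        assert left == pytest.approx(right, abs=1e-12)

    @pytest.mark.parametrize("rule", ["silverman", "scott", 0.25])
    def test_mass_conservation(self, rule):
        rng = np.random.default_rng(11)
        curve = kde(rng.normal(50, 5, 400), bandwidth_rule=rule)
        assert 0.99 <= curve.integral() <= 1.01
        assert np.all(curve.density >= 0)

    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(2)
        curve = kde(rng.standard_normal(10_000))
        assert curve.at(0.0) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=0.05)

    def test_zero_variance_with_rule_rejected_fixed_allowed(self):
        with pytest.raises(DegenerateInputError):
            kde([3.0, 3.0, 3.0], bandwidth_rule="silverman")
        curve = kde([3.0, 3.0, 3.0], bandwidth_rule=0.1)
        assert 0.99 <= curve.integral() <= 1.01

    def test_cutoff_annotations_carried(self):
        curve = kde([1.0, 2.0, 3.0], cutoffs=(22.0,), parameter=Parameter.RR)
        assert curve.cutoffs == (22.0,) and curve.parameter is Parameter.RR

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_n"):
            kde([1.0, 2.0], grid_n=8)
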