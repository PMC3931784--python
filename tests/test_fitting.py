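"""Cost-function metrics, the composite cost and the pattern-search optimizer."""

import math

import numpy as np
import pytest

from axonome.environment import GrowthField
from axonome.fitting import (
    CostEvaluator,
    PatternSearchOptions,
    compare_sets,
    densify,
    dv_histogram,
    histogram_distance,
    mean_tortuosity,
    pattern_search,
    tortuosity,
)
from axonome.generalize import PairedSample, fit_ecdf
from axonome.growth import SensitivityVector
from axonome.fixtures import make_reference_axons


class TestDensify:
    def test_two_points_ten_apart(self):
        out = densify(np.array([[0.0, 0.0], [10.0, 0.0]]))
        assert len(out) == 11
        assert np.allclose(np.diff(out[:, 0]), 1.0)

    def test_unit_spaced_input_unchanged(self):
        pts = np.column_stack([np.arange(8.0), np.zeros(8)])
        assert np.allclose(densify(pts), pts)

    def test_l_shape_keeps_corner(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0]])
        out = densify(pts)
        assert len(out) == 11
        assert any(np.allclose(p, [5.0, 0.0]) for p in out)
        arc = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert arc == pytest.approx(10.0)

    def test_duplicate_points_dropped(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        out = densify(pts)
        assert len(out) == 4


class TestDVHistogram:
    def test_single_level_axon(self):
        axon = np.column_stack([np.arange(101.0), np.full(101, 75.0)])
        h = dv_histogram([axon])
        idx = 7  # bin [70, 80)
        assert h.proportions[idx] == pytest.approx(1.0)

    def test_two_axons_split_evenly(self):
        a = np.column_stack([np.arange(50.0), np.full(50, 35.0)])
        b = np.column_stack([np.arange(50.0), np.full(50, 135.0)])
        h = dv_histogram([a, b])
        assert h.proportions[3] == pytest.approx(0.5)
        assert h.proportions[13] == pytest.approx(0.5)

    def test_vertical_axon_against_per_point_count(self):
        ys = np.arange(25.0, 145.0 + 0.5, 1.0)
        axon = np.column_stack([np.full_like(ys, 500.0), ys])
        h = dv_histogram([axon])
        counts, _ = np.histogram(ys, bins=h.edges)  # direct per-point count
        assert np.allclose(h.proportions, counts / counts.sum())

    def test_negative_side_folds_onto_dv_axis(self):
        a = np.column_stack([np.arange(40.0), np.full(40, -75.0)])
        h = dv_histogram([a])
        assert h.proportions[7] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dv_histogram([])


class TestHistogramDistance:
    def _hist(self, sets):
        return dv_histogram(sets)

    def test_zero_iff_identical_and_symmetric(self):
        a = np.column_stack([np.arange(60.0), np.full(60, 55.0)])
        b = np.column_stack([np.arange(60.0), np.full(60, 95.0)])
        ha, hb = self._hist([a]), self._hist([b])
        assert histogram_distance(ha, ha) == 0.0
        assert histogram_distance(ha, hb) == histogram_distance(hb, ha) > 0

    def test_disjoint_support_reaches_maximum(self):
        # direct summation: sum p_i + sum q_i = 2 when supports are disjoint
        a = np.column_stack([np.arange(60.0), np.full(60, 30.0)])
        b = np.column_stack([np.arange(60.0), np.full(60, 130.0)])
        assert histogram_distance(self._hist([a]), self._hist([b])) == pytest.approx(2.0)


class TestTortuosity:
    def test_straight_line_is_one(self):
        pts = np.column_stack([np.linspace(0, 400, 41), np.zeros(41)])
        assert tortuosity(pts) == pytest.approx(1.0)

    def test_semicircle_approaches_half_pi(self):
        r = 400.0
        th = np.linspace(0, math.pi, 2000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        assert tortuosity(pts) == pytest.approx(math.pi / 2, rel=0.01)

    def test_resampling_invariance_on_straight_lines(self):
        for n in (2, 7, 500):
            pts = np.column_stack([np.linspace(0, 333, n), np.linspace(0, 50, n)])
            assert tortuosity(pts) == pytest.approx(1.0)

    def test_closed_loop_excluded_from_mean(self):
        th = np.linspace(0, 2 * math.pi, 100)
        loop = np.column_stack([50 * np.cos(th), 50 * np.sin(th)])
        straight = np.column_stack([np.linspace(0, 100, 11), np.zeros(11)])
        assert mean_tortuosity([loop, straight]) == pytest.approx(1.0)


def _toy_evaluator(seed=0, n_model=12):
    field = GrowthField(rc_extent=(0.0, 6000.0))
    true = SensitivityVector(1.0, -4.0, -4.0, 0.15, 1)
    rng = np.random.default_rng(99)
    lengths = rng.uniform(250, 450, 20)
    starts = PairedSample(
        points=rng.uniform([40, -100], [110, -80], size=(15, 2)),
        bounds=((25.0, 145.0), (-180.0, 0.0)),
    )
    real = make_reference_axons(true, 25, fit_ecdf(lengths), starts, field, rng)
    return CostEvaluator(
        real_axons=[t.points for t in real],
        length_cdf=fit_ecdf(lengths),
        start_sample=starts,
        field=field,
        n_model_axons=n_model,
        seed=seed,
    ), true


class TestCost:
    def test_self_comparison_is_zero(self):
        ev, _ = _toy_evaluator()
        br = ev.evaluate_with_model(list(ev.real_axons))
        assert br.Q == 0.0
        assert br.F == 0.0
        assert br.T_model == pytest.approx(br.T_real)

    def test_breakdown_identity(self):
        ev, true = _toy_evaluator()
        br = ev(np.array([1.0, -4.0, -4.0, 0.15]))
        assert br.F == pytest.approx(br.Q + br.kappa * (br.T_real - br.T_model) ** 2)
        assert br.F >= 0

    def test_translation_invariance(self):
        # shifting all axons rostro-caudally changes neither histogram nor
        # tortuosity, hence not the cost
        ev, _ = _toy_evaluator()
        shifted = [p + np.array([250.0, 0.0]) for p in ev.real_axons]
        assert ev.evaluate_with_model(shifted).F == pytest.approx(0.0)

    def test_repeated_evaluations_right_skewed_low_cost_mass(self):
        # The stochastic cost at the true parameters fluctuates from
        # evaluation to evaluation; its distribution is right-skewed with
        # the bulk of the mass at low cost values and a thin high-cost tail.
        from scipy import stats as sps

        rng = np.random.default_rng(99)
        field = GrowthField(rc_extent=(0.0, 6000.0))
        true = SensitivityVector(1.0, -4.0, -4.0, 0.15, 1)
        lengths = np.clip(rng.lognormal(6.3, 0.6, 46), 110, 1450)
        starts = PairedSample(
            points=rng.uniform([40, -100], [110, -80], size=(15, 2)),
            bounds=((25.0, 145.0), (-180.0, 0.0)),
        )
        real = make_reference_axons(true, 30, fit_ecdf(lengths), starts,
                                    field, rng)
        ev = CostEvaluator(
            real_axons=[t.points for t in real], length_cdf=fit_ecdf(lengths),
            start_sample=starts, field=field, n_model_axons=40, seed=1,
        )
        x = np.array([1.0, -4.0, -4.0, 0.15])
        fs = np.array([ev(x).F for _ in range(60)])
        assert sps.skew(fs) > 0
        midpoint = 0.5 * (fs.min() + fs.max())
        assert np.mean(fs < midpoint) >= 0.6

    def test_nonfinite_parameters_give_infinite_cost(self):
        ev, _ = _toy_evaluator()
        assert ev(np.array([np.nan, 0, 0, 0])).F == np.inf


class TestPatternSearch:
    def test_recovers_quadratic_minimum(self):
        target = np.array([0.7, -2.0, 1.5, 0.2])

        def cost(x):
            return float(((x - target) ** 2).sum())

        opts = PatternSearchOptions(initial_mesh=1.0, mesh_tolerance=1e-5,
                                    max_evaluations=5000)
        res = pattern_search(cost, np.zeros(4), opts)
        assert res.progressed
        assert np.all(np.abs(res.x - target) < 1e-3)

    def test_constant_cost_returns_start(self):
        res = pattern_search(lambda x: 1.0, np.array([1.0, 2.0, 3.0, 4.0]),
                             PatternSearchOptions(max_evaluations=200))
        assert not res.progressed
        assert np.allclose(res.x, [1.0, 2.0, 3.0, 4.0])
        assert res.mesh < PatternSearchOptions().mesh_tolerance

    def test_budget_of_one_returns_start(self):
        res = pattern_search(lambda x: float((x ** 2).sum()), np.ones(4),
                             PatternSearchOptions(max_evaluations=1))
        assert not res.progressed and np.allclose(res.x, 1.0)

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            PatternSearchOptions(expansion=0.9)
        with pytest.raises(ValueError):
            PatternSearchOptions(mesh_tolerance=0.0)


class TestCompareSets:
    def _straightish(self, rng, y0, n=20):
        xs = np.linspace(0, 300, 31)
        return [
            np.column_stack([xs, y0 + rng.normal(0, 2.0, 31).cumsum() * 0.1])
            for _ in range(n)
        ]

    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        sets = self._straightish(rng, 60.0)
        rep = compare_sets(sets, sets)
        assert rep.t_statistic == 0.0
        assert rep.t_pvalue == 1.0
        assert rep.chi2_statistic == 0.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        a = self._straightish(rng, 40.0)
        wiggly = [
            np.column_stack([
                np.linspace(0, 300, 301),
                120.0 + 30 * np.sin(np.linspace(0, 20, 301)),
            ])
            for _ in range(20)
        ]
        rep = compare_sets(a, wiggly)
        assert rep.t_pvalue < 0.001
        assert rep.chi2_pvalue < 0.001

    def test_too_small_sets_rejected(self):
        rng = np.random.default_rng(2)
        a = self._straightish(rng, 60.0)
        with pytest.raises(ValueError):
            compare_sets(a[:1], a)

    def test_caveat_attached(self):
        rng = np.random.default_rng(3)
        a = self._straightish(rng, 60.0)
        assert "not independent" in compare_sets(a, a).caveat
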