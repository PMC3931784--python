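"""The difference-equation stepper, stage machine and fixed-point analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonome.environment import GrowthField
from axonome.growth import (
    DELTA,
    GrowthState,
    NeuronTypeSpec,
    NoFixedPointError,
    SensitivitySchedule,
    SensitivityVector,
    fixed_point,
    grow_main_only,
    grow_primary,
    grow_secondary,
    sensitivity_at,
    step,
)

ZERO = SensitivityVector()


class TestStep:
    def test_pure_stiffness_goes_straight(self, field, rng):
        s = GrowthState(x=1000.0, y=60.0, theta=math.pi, stage="main")
        out = step(s, ZERO, field, rng)
        assert out.x == pytest.approx(999.0)
        assert out.y == pytest.approx(60.0)
        assert out.theta == pytest.approx(math.pi)
        assert out.step_index == 1 and out.path_length == pytest.approx(DELTA)

    def test_dorsal_attraction_turns_dorsally(self, field, rng):
        # gamma_dorsal > 0 only, heading rostral on the +y side: the next
        # point must move dorsally (y increases)
        s = GrowthState(x=1000.0, y=60.0, theta=math.pi, stage="main")
        sens = SensitivityVector(gamma_dorsal=2.0)
        out = step(s, sens, field, rng)
        assert out.y > 60.0

    def test_dorsal_repulsion_turns_ventrally(self, field, rng):
        s = GrowthState(x=1000.0, y=60.0, theta=math.pi, stage="main")
        out = step(s, SensitivityVector(gamma_dorsal=-2.0), field, rng)
        assert out.y < 60.0

    def test_outside_field_raises(self, field, rng):
        s = GrowthState(x=-5.0, y=60.0, theta=0.0)
        with pytest.raises(ValueError):
            step(s, ZERO, field, rng)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SensitivityVector(gamma_dorsal=math.nan)

    @given(
        theta=st.floats(-math.pi, math.pi),
        y=st.floats(-140, 140),
        gd=st.floats(-5, 5),
        gv=st.floats(-5, 5),
        alpha=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_step_length_always_delta(self, theta, y, gd, gv, alpha):
        field = GrowthField()  # no barriers
        rng = np.random.default_rng(0)
        s = GrowthState(x=1000.0, y=y, theta=theta, stage="main")
        out = step(s, SensitivityVector(1.0, gd, gv, alpha), field, rng)
        d = math.hypot(out.x - s.x, out.y - s.y)
        assert d == pytest.approx(DELTA, abs=1e-9)


class TestSensitivitySchedule:
    SCHED = SensitivitySchedule(
        start=SensitivityVector(4.0, 4.0, 4.0, alpha=0.3),
        main=SensitivityVector(0.0, 0.0, 0.0, alpha=0.1),
        decay_rates=(math.log(2), math.log(2), math.log(2)),
    )

    def test_at_zero_equals_start(self):
        v = sensitivity_at(self.SCHED, 0.0)
        assert v.gamma_rostral == pytest.approx(4.0)

    def test_limit_equals_main(self):
        v = sensitivity_at(self.SCHED, 1e4)
        assert abs(v.gamma_dorsal) < 1e-9

    def test_half_life(self):
        # gamma_start=4, gamma_main=0, lambda=ln2 per um, L=1 -> 2.0
        v = sensitivity_at(self.SCHED, 1.0)
        assert v.gamma_ventral == pytest.approx(2.0)

    def test_alpha_taken_from_main(self):
        assert sensitivity_at(self.SCHED, 0.0).alpha == pytest.approx(0.1)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_at(self.SCHED, -1.0)


class TestGrowPrimary:
    def test_point_count(self, ain_spec, field, rng):
        t = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 250.0, field, rng)
        assert len(t) == 251

    def test_exact_step_spacing(self, ain_spec, field, rng):
        t = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 400.0, field, rng)
        d = np.linalg.norm(np.diff(t.points, axis=0), axis=1)
        assert np.all(np.abs(d - DELTA) < 1e-9)

    def test_stage_monotonic(self, ain_spec, field, rng):
        t = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 500.0, field, rng)
        order = {"outgrowth": 0, "orientation": 1, "main": 2}
        codes = [order[s] for s in t.stages]
        assert codes == sorted(codes)

    def test_main_switch_at_100um_longitudinal_offset(self, ain_spec, field, rng):
        for _ in range(5):
            t = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 500.0, field, rng)
            offsets = np.abs(t.x - t.x[0])
            first_main = t.stages.index("main")
            assert offsets[first_main] >= 100.0
            assert np.all(offsets[:first_main] < 100.0)

    def test_crossing_reaches_opposite_side(self, cin_spec, field):
        rng = np.random.default_rng(0)
        t = grow_primary(cin_spec, (1500.0, 60.0), -90.0, 700.0, field, rng)
        assert t.crossed_at is not None
        assert np.any(t.y < -field.floorplate_halfwidth)

    def test_crossing_floorplate_run_contiguous(self, cin_spec, field):
        # exactly one contiguous run of points inside the floor plate
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = grow_primary(cin_spec, (1500.0, rng.uniform(35, 130)),
                             rng.uniform(-110, -70), 800.0, field, rng)
            inside = (np.abs(t.y) < field.floorplate_halfwidth).astype(int)
            starts = np.sum(np.diff(np.r_[0, inside]) == 1)
            assert starts == 1

    def test_truncation_at_rostral_boundary(self, ain_spec, field, rng):
        # an ascending axon started near x=0 runs out of field
        t = grow_primary(ain_spec, (150.0, 60.0), -80.0, 2000.0, field, rng)
        assert t.truncated
        assert len(t) < 2001
        assert t.x.min() >= field.rc_extent[0]

    def test_invalid_origin_and_length(self, ain_spec, field, rng):
        with pytest.raises(ValueError):
            grow_primary(ain_spec, (1500.0, 60.0), -80.0, 0.0, field, rng)
        with pytest.raises(ValueError):
            grow_primary(ain_spec, (-10.0, 60.0), -80.0, 100.0, field, rng)


class TestGrowSecondary:
    def test_branch_zero_starts_at_first_main_point(self, ain_spec, field, rng):
        p = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 500.0, field, rng)
        s = grow_secondary(p, ain_spec, 0.0, 10.0, 100.0, field, rng)
        assert np.allclose(s.points[0], p.points[p.main_start])
        assert s.branch_point == p.main_start

    def test_secondary_descends_when_primary_ascends(self, ain_spec, field, rng):
        p = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 500.0, field, rng)
        s = grow_secondary(p, ain_spec, 20.0, 0.0, 300.0, field, rng)
        assert s.x[-1] - s.x[0] > 0  # net caudal displacement

    def test_zero_noise_zero_sensitivity_is_straight(self, ain_spec, field, rng):
        import dataclasses

        p = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 400.0, field, rng)
        spec = dataclasses.replace(ain_spec, secondary_params=ZERO)
        s = grow_secondary(p, spec, 10.0, 30.0, 50.0, field, rng)
        d = s.points[-1] - s.points[0]
        assert math.degrees(math.atan2(d[1], d[0])) == pytest.approx(30.0, abs=1e-6)

    def test_branch_requires_crossed_primary(self, cin_spec, field, rng):
        # a commissural primary that never crossed cannot carry a branch
        short = grow_primary(cin_spec, (1500.0, 130.0), -90.0, 30.0, field, rng)
        assert short.crossed_at is None
        with pytest.raises(ValueError):
            grow_secondary(short, cin_spec, 0.0, 0.0, 100.0, field, rng)

    def test_branch_beyond_primary_rejected(self, ain_spec, field, rng):
        p = grow_primary(ain_spec, (1500.0, 60.0), -80.0, 300.0, field, rng)
        with pytest.raises(ValueError):
            grow_secondary(p, ain_spec, 1e4, 0.0, 100.0, field, rng)


class TestFixedPoint:
    def test_symmetric_cues_balance_midway(self):
        # sources at 145 and 5 with equal decay and equal repulsion: the
        # torques cancel midway between the source lines
        f = GrowthField()
        y = fixed_point(SensitivityVector(0.0, -3.0, -3.0), f)
        assert y == pytest.approx(75.0, abs=1e-6)

    def test_one_sided_torque_has_no_interior_balance(self):
        f = GrowthField()
        with pytest.raises(NoFixedPointError):
            fixed_point(SensitivityVector(0.0, 3.0, 0.0), f)

    def test_unequal_gains_shift_the_balance(self):
        f = GrowthField()
        y_sym = fixed_point(SensitivityVector(0.0, -3.0, -3.0), f)
        y_dorsalish = fixed_point(SensitivityVector(0.0, -1.0, -4.0), f)
        assert y_dorsalish > y_sym  # weaker dorsal repulsion: rests higher

    def test_zero_noise_growth_converges_to_fixed_point(self, big_field):
        rng = np.random.default_rng(2)
        sens = SensitivityVector(1.0, -4.0, -4.0, 0.0, 1)
        ystar = fixed_point(sens, big_field)
        t = grow_main_only(sens, (big_field.rc_extent[1], 40.0), 180.0, 10000,
                           big_field, rng)
        assert abs(t.y[-1] - ystar) < 1.0
        # |y - y*| eventually monotonically decreasing
        err = np.abs(t.y - ystar)
        tail = err[-2000:]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_noise_masks_the_attractor(self, big_field):
        # Terminal spread across axons with optimized-scale noise is much
        # wider than the zero-noise spread.
        def spread(alpha, seed):
            rng = np.random.default_rng(seed)
            finals = []
            for i in range(50):
                s = SensitivityVector(1.0, -4.0, -4.0, alpha, 1)
                t = grow_main_only(s, (20000.0, 40.0 + i * 2.0 % 100), 180.0,
                                   6000, big_field, rng)
                finals.append(t.y[-1])
            return np.std(finals)

        assert spread(0.15, 3) >= 5.0 * spread(0.0, 3)

    def test_increasing_dorsal_gain_never_lowers_mean_y(self, big_field):
        # attraction semantics: more dorsal-ward torque -> same or higher
        # mean main-stage dorso-ventral position (fixed seed)
        means = []
        for gd in (-5.0, -3.0, -1.0):
            rng = np.random.default_rng(7)
            s = SensitivityVector(1.0, gd, -4.0, 0.1, 1)
            t = grow_main_only(s, (6000.0, 70.0), 180.0, 2000, big_field, rng)
            means.append(t.y.mean())
        assert means == sorted(means)


class TestSpecValidation:
    def test_crossing_needs_ventral_attraction(self):
        sched = SensitivitySchedule(start=ZERO, main=ZERO)
        with pytest.raises(ValueError):
            NeuronTypeSpec(
                name="bad", crossing=True, primary_direction="ascending",
                outgrowth_params=ZERO, schedule=sched,
            )
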