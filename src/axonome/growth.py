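"""Stochastic difference-equation axon growth and the stage machine.

An axon tip is a point ``(x, y)`` with a heading ``theta`` that advances in
fixed 1 µm steps.  At every step the heading is deflected by the projection
of each guidance cue's gradient (or polarity direction) onto the unit normal
of the current heading, weighted by a signed, neuron-type-specific
sensitivity, plus a uniform random perturbation::

    theta' = theta + rc_sign * g_R * (G_R . n) + g_D * (G_D . n)
                   + g_V * (G_V . n) + xi,     xi ~ Uniform[-alpha, +alpha]
    x' = x + delta * cos(theta'),   y' = y + delta * sin(theta')

where ``n`` is the heading rotated +90° (counter-clockwise).  Positive
sensitivities are attractive (the tip turns toward the cue source), negative
repulsive.  ``rc_sign = +1`` selects ascending (rostral-going) response to
the polarity cue, ``-1`` descending.

Primary axons pass through three irreversible stages: a brief *outgrowth*
stage (for commissural neurons: ventral growth through the floor plate to
the opposite side), an *orientation* stage in which sensitivities relax
exponentially from a start vector to the main vector as a function of path
length, and a *main* longitudinal stage with fixed sensitivities.  Secondary
axons branch off the primary and run a single main stage in the opposite
longitudinal direction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np

from .environment import (
    LN10,
    GrowthField,
    OutOfFieldError,
    barrier_hit,
)

__all__ = [
    "GrowthState",
    "SensitivityVector",
    "SensitivitySchedule",
    "OrientationTrigger",
    "AnatomySamples",
    "NeuronTypeSpec",
    "AxonTrajectory",
    "NoFixedPointError",
    "step",
    "sensitivity_at",
    "grow_primary",
    "grow_secondary",
    "grow_main_only",
    "fixed_point",
    "DELTA",
]

#: Axon elongation per step, µm.
DELTA = 1.0

#: Longitudinal offset from the stage-reference point at which the
#: orientation stage hands over to the main stage, µm.
MAIN_SWITCH_OFFSET = 100.0

Stage = Literal["outgrowth", "orientation", "main"]
_STAGE_ORDER = {"outgrowth": 0, "orientation": 1, "main": 2}


class NoFixedPointError(ValueError):
    """The dorsal/ventral torques do not balance inside the marginal zone."""


@dataclass(frozen=True)
class GrowthState:
    """Snapshot of one growing axon tip."""

    x: float
    y: float
    theta: float  # radians, wrapped to (-pi, pi]; 0 = caudal (+x), pi = rostral
    step_index: int = 0
    path_length: float = 0.0  # µm since the reference event
    stage: Stage = "outgrowth"
    crossed: bool = False

    def replace(self, **kw) -> "GrowthState":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SensitivityVector:
    """Signed cue sensitivities plus the angular-noise half-width."""

    gamma_rostral: float = 0.0
    gamma_dorsal: float = 0.0
    gamma_ventral: float = 0.0
    alpha: float = 0.0  # radians; xi ~ Uniform[-alpha, +alpha]
    rc_sign: int = 1  # +1 ascending (rostral-going), -1 descending

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.rc_sign not in (-1, 1):
            raise ValueError("rc_sign must be +1 or -1")
        for g in (self.gamma_rostral, self.gamma_dorsal, self.gamma_ventral, self.alpha):
            if not math.isfinite(g):
                raise ValueError("sensitivity parameters must be finite")


@dataclass(frozen=True)
class SensitivitySchedule:
    """Exponential relaxation of sensitivities during the orientation stage.

    Per cue, ``gamma(L) = gamma_main + (gamma_start - gamma_main) *
    exp(-lambda * L)`` where ``L`` is the path length since orientation
    onset.  ``alpha`` and ``rc_sign`` are taken from the main vector and are
    not scheduled.
    """

    start: SensitivityVector
    main: SensitivityVector
    decay_rates: tuple[float, float, float] = (0.05, 0.05, 0.05)  # 1/µm (R, D, V)

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.decay_rates):
            raise ValueError("decay_rates must be >= 0")


@dataclass(frozen=True)
class OrientationTrigger:
    """Rule ending the outgrowth stage.

    ``longitudinal_offset``: outgrowth ends when |x - x_origin| reaches
    ``value`` µm (uncrossed types; the stage is very short).
    ``floorplate_exit``: outgrowth ends when the tip emerges from the floor
    plate on the side opposite the origin (commissural types).
    """

    kind: Literal["longitudinal_offset", "floorplate_exit"]
    value: float = 5.0


@dataclass
class AnatomySamples:
    """Measured (or synthetic) anatomical samples for one neuron type."""

    lengths: np.ndarray  # axon lengths, µm
    start_dv_angle: object  # PairedSample of (dv position, outgrowth angle °)
    branch_distance: np.ndarray | None = None  # µm along the eligible region
    branch_angle: np.ndarray | None = None  # degrees
    dendrite_extent: object | None = None  # PairedSample of (d_low, d_high)


@dataclass
class NeuronTypeSpec:
    """Everything needed to grow the axons of one neuron type."""

    name: str
    crossing: bool
    primary_direction: Literal["ascending", "descending"]
    outgrowth_params: SensitivityVector
    schedule: SensitivitySchedule
    secondary_params: SensitivityVector | None = None
    orientation_trigger: OrientationTrigger = dc_field(
        default_factory=lambda: OrientationTrigger("longitudinal_offset", 5.0)
    )
    samples: AnatomySamples | None = None
    population: int = 0
    synapse_class: Literal["sensory", "non-sensory"] = "non-sensory"
    has_secondary: bool = True

    def __post_init__(self) -> None:
        if self.crossing and self.outgrowth_params.gamma_ventral <= 0:
            raise ValueError(
                "crossing neurons need ventral attraction (gamma_ventral > 0) "
                "during outgrowth to reach the floor plate"
            )


class AxonTrajectory:
    """Ordered 2-D tip positions at DELTA spacing with stage labels."""

    def __init__(
        self,
        points: np.ndarray,
        stages: list[str],
        neuron_id: str = "",
        kind: Literal["primary", "secondary"] = "primary",
        branch_point: int | None = None,
        truncated: bool = False,
        crossed_at: int | None = None,
        main_start: int | None = None,
    ) -> None:
        self.points = np.asarray(points, dtype=float)
        self.stages = list(stages)
        self.neuron_id = neuron_id
        self.kind = kind
        self.branch_point = branch_point
        self.truncated = truncated
        self.crossed_at = crossed_at  # index of floor-plate exit, if crossing
        self.main_start = main_start  # index of the first main-stage point
        if len(self.points) != len(self.stages):
            raise ValueError("points and stage labels must align")
        order = [_STAGE_ORDER[s] for s in self.stages]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("stage labels must be non-decreasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def stage_points(self, stage: str) -> np.ndarray:
        mask = np.array([s == stage for s in self.stages])
        return self.points[mask]


# ---------------------------------------------------------------------------
# the stepper


def _torque(
    x: float, y: float, theta: float, sens: SensitivityVector, field: GrowthField
) -> float:
    """Deterministic heading deflection from the three cues at (x, y).

    Each cue's gradient (or polarity direction) is projected onto the unit
    normal of the heading, n = (-sin theta, cos theta).
    """
    sin_t = math.sin(theta)
    cos_t = math.cos(theta)
    # rostral polarity: direction (-1, 0), magnitude 1 -> projection = sin(theta)
    dtheta = sens.rc_sign * sens.gamma_rostral * sin_t
    side = 1.0 if y >= 0.0 else -1.0
    ay = abs(y)
    # dorsal cue: gradient (0, side * m_D), m_D = decay*ln10*10^(-decay*dist)
    if sens.gamma_dorsal != 0.0:
        m_d = field.dorsal_decay * LN10 * 10.0 ** (
            -field.dorsal_decay * (field.dv_halfwidth - ay)
        )
        dtheta += sens.gamma_dorsal * side * m_d * cos_t
    # ventral cue: gradient (0, -side * m_V) outside the source strip
    if sens.gamma_ventral != 0.0 and ay > field.ventral_source_offset:
        m_v = field.ventral_decay * LN10 * 10.0 ** (
            -field.ventral_decay * (ay - field.ventral_source_offset)
        )
        dtheta -= sens.gamma_ventral * side * m_v * cos_t
    return dtheta


def _wrap(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = math.fmod(theta + math.pi, 2.0 * math.pi)
    if t <= 0.0:
        t += 2.0 * math.pi
    return t - math.pi


def _advance(
    x: float,
    y: float,
    theta: float,
    stage: str,
    sens: SensitivityVector,
    field: GrowthField,
    xi: float,
) -> tuple[float, float, float]:
    """One raw step; returns (x', y', theta') before barrier handling."""
    theta2 = _wrap(theta + _torque(x, y, theta, sens, field) + xi)
    return x + DELTA * math.cos(theta2), y + DELTA * math.sin(theta2), theta2


def _deflect(x, y, theta2, rc_sign: int) -> tuple[float, float, float]:
    """Retake a blocked step longitudinally, preserving the step length."""
    c = math.cos(theta2)
    if c > 0:
        t = 0.0
    elif c < 0:
        t = math.pi
    else:
        # tie: fall back on the configured growth direction
        # (+1 ascending = rostral = pi; -1 descending = caudal = 0)
        t = math.pi if rc_sign > 0 else 0.0
    return x + DELTA * math.cos(t), y, t


def step(
    state: GrowthState,
    sens: SensitivityVector,
    field: GrowthField,
    rng: np.random.Generator,
) -> GrowthState:
    """Advance one axon tip by one DELTA step, respecting barriers.

    The new position is always exactly DELTA from the old one.  If the full
    step would cross an active barrier (or leave the dorso-ventral extent of
    the field, whose edge is the cut dorsal midline that no axon crosses),
    the step is turned longitudinally on contact: the heading is replaced by
    the longitudinal direction matching its rostro-caudal component (ties
    broken toward the neuron's configured growth direction) and the step
    retaken from the previous point.
    """
    if not field.contains(state.x, state.y):
        raise OutOfFieldError(f"state at ({state.x}, {state.y}) outside the field")
    xi = float(rng.uniform(-sens.alpha, sens.alpha)) if sens.alpha > 0 else 0.0
    nx, ny, nth = _advance(state.x, state.y, state.theta, state.stage, sens, field, xi)
    blocked = abs(ny) > field.dv_halfwidth or barrier_hit(
        state.y, ny, state.x, state.stage, field
    )
    if blocked:
        nx, ny, nth = _deflect(state.x, state.y, nth, sens.rc_sign)
    return state.replace(
        x=nx,
        y=ny,
        theta=nth,
        step_index=state.step_index + 1,
        path_length=state.path_length + DELTA,
    )


def sensitivity_at(schedule: SensitivitySchedule, L: float) -> SensitivityVector:
    """Orientation-stage sensitivities after path length ``L`` µm.

    gamma_i(L) = gamma_i_main + (gamma_i_start - gamma_i_main) * exp(-lambda_i L)
    """
    if L < 0:
        raise ValueError("path length must be >= 0")
    s, m, lam = schedule.start, schedule.main, schedule.decay_rates
    return SensitivityVector(
        gamma_rostral=m.gamma_rostral
        + (s.gamma_rostral - m.gamma_rostral) * math.exp(-lam[0] * L),
        gamma_dorsal=m.gamma_dorsal
        + (s.gamma_dorsal - m.gamma_dorsal) * math.exp(-lam[1] * L),
        gamma_ventral=m.gamma_ventral
        + (s.gamma_ventral - m.gamma_ventral) * math.exp(-lam[2] * L),
        alpha=m.alpha,
        rc_sign=m.rc_sign,
    )


# ---------------------------------------------------------------------------
# whole-axon growth


def _grow(
    x0: float,
    y0: float,
    theta0: float,
    n_steps: int,
    sens_for: "callable",
    field: GrowthField,
    rng: np.random.Generator,
    stage0: str,
) -> tuple[np.ndarray, list[str], bool, dict]:
    """Shared growth loop.  ``sens_for(k, x, y, stage, info)`` returns the
    (possibly updated) ``(sens, stage)`` for the step leaving point ``k``;
    stage transitions are evaluated at the current tip, so the point that
    satisfies a transition rule is itself relabelled with the new stage.
    ``info`` is a mutable dict the stage machine uses for its bookkeeping.
    """
    xs = [x0]
    ys = [y0]
    stages = [stage0]
    x, y, theta, stage = x0, y0, theta0, stage0
    info: dict = {}
    truncated = False
    lo, hi = field.rc_extent
    for k in range(n_steps):
        sens, stage = sens_for(k, x, y, stage, info)
        stages[-1] = stage
        xi = float(rng.uniform(-sens.alpha, sens.alpha)) if sens.alpha > 0 else 0.0
        nx, ny, nth = _advance(x, y, theta, stage, sens, field, xi)
        if abs(ny) > field.dv_halfwidth or barrier_hit(y, ny, x, stage, field):
            nx, ny, nth = _deflect(x, y, nth, sens.rc_sign)
        if not lo <= nx <= hi:
            truncated = True
            break
        x, y, theta = nx, ny, nth
        xs.append(x)
        ys.append(y)
        stages.append(stage)
    return np.column_stack([xs, ys]), stages, truncated, info


def grow_primary(
    spec: NeuronTypeSpec,
    origin: tuple[float, float],
    outgrowth_angle_deg: float,
    length: float,
    field: GrowthField,
    rng: np.random.Generator,
    neuron_id: str = "",
) -> AxonTrajectory:
    """Grow a whole primary axon through its outgrowth/orientation/main stages.

    ``origin`` is the soma position; ``outgrowth_angle_deg`` the initial
    heading in degrees (180 = rostral).  Growth terminates when the total
    path length reaches ``length`` (so the trajectory has ``length/DELTA + 1``
    points) or, truncated, when the tip leaves the rostro-caudal extent.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    x0, y0 = origin
    if not field.contains(x0, y0):
        raise OutOfFieldError(f"origin ({x0}, {y0}) outside the field")
    y0 = field.nudge_off_barriers(y0)
    theta0 = math.radians(outgrowth_angle_deg)
    origin_side = 1.0 if y0 >= 0 else -1.0
    trig = spec.orientation_trigger
    fp = field.floorplate_halfwidth

    def sens_for(k, x, y, stage, info):
        if stage == "outgrowth":
            if spec.crossing:
                if y * origin_side < 0 and abs(y) > fp:
                    # emerged from the floor plate on the opposite side
                    info["crossed_at"] = k
                    info["ref_x"] = x
                    info["orient_start"] = k
                    stage = "orientation"
            else:
                if trig.kind == "longitudinal_offset" and abs(x - x0) >= trig.value:
                    info["orient_start"] = k
                    info["ref_x"] = x0  # main switch measured from the origin
                    stage = "orientation"
        if stage == "orientation":
            if abs(x - info["ref_x"]) >= MAIN_SWITCH_OFFSET:
                stage = "main"
                info["main_start"] = k
        if stage == "outgrowth":
            return spec.outgrowth_params, stage
        if stage == "orientation":
            L = (k - info["orient_start"]) * DELTA
            return sensitivity_at(spec.schedule, L), stage
        return spec.schedule.main, stage

    n_steps = int(round(length / DELTA))
    points, stages, truncated, info = _grow(
        x0, y0, theta0, n_steps, sens_for, field, rng, "outgrowth"
    )
    crossed_at = info.get("crossed_at")
    main_start = info.get("main_start")
    return AxonTrajectory(
        points,
        stages,
        neuron_id=neuron_id,
        kind="primary",
        truncated=truncated,
        crossed_at=crossed_at,
        main_start=main_start,
    )


def grow_secondary(
    primary: AxonTrajectory,
    spec: NeuronTypeSpec,
    branch_distance: float,
    branch_angle_deg: float,
    length: float,
    field: GrowthField,
    rng: np.random.Generator,
) -> AxonTrajectory:
    """Grow a secondary axon from a branch point on the primary.

    ``branch_distance`` is arc length along the primary measured from the
    start of the eligible branching region: the first main-stage point for
    uncrossed primaries and the floor-plate exit point for crossing ones
    (a commissural secondary arises only after the primary has crossed).
    The secondary runs a single main stage in the longitudinal direction
    opposite to the primary.
    """
    if spec.crossing:
        if primary.crossed_at is None:
            raise ValueError("branch on a crossing primary requires a crossed primary")
        ref = primary.crossed_at
    else:
        if primary.main_start is None:
            raise ValueError("primary has no main stage to branch from")
        ref = primary.main_start
    if branch_distance < 0:
        raise ValueError("branch_distance must be >= 0")
    idx = ref + int(round(branch_distance / DELTA))
    if idx >= len(primary):
        raise ValueError("branch_distance beyond the primary's path length")
    bx, by = primary.points[idx]
    sens = spec.secondary_params if spec.secondary_params is not None else spec.schedule.main
    # secondary runs opposite to the primary's longitudinal direction
    primary_sign = 1 if spec.primary_direction == "ascending" else -1
    sens = dataclasses.replace(sens, rc_sign=-primary_sign)

    def sens_for(k, x, y, stage, info):
        return sens, "main"

    n_steps = int(round(length / DELTA))
    points, stages, truncated, _ = _grow(
        bx, by, math.radians(branch_angle_deg), n_steps, sens_for, field, rng, "main"
    )
    return AxonTrajectory(
        points,
        stages,
        neuron_id=primary.neuron_id,
        kind="secondary",
        branch_point=idx,
        truncated=truncated,
    )


def grow_main_only(
    sens: SensitivityVector,
    origin: tuple[float, float],
    angle_deg: float,
    length: float,
    field: GrowthField,
    rng: np.random.Generator,
    neuron_id: str = "",
) -> AxonTrajectory:
    """Grow a single-stage main axon with fixed sensitivities.

    This is the configuration used when fitting main-stage parameters and in
    the longitudinal-growth analyses: axons start at a sampled dorso-ventral
    position and grow longitudinally with constant sensitivities.
    """

    def sens_for(k, x, y, stage, info):
        return sens, "main"

    x0, y0 = origin
    if not field.contains(x0, y0):
        raise OutOfFieldError(f"origin ({x0}, {y0}) outside the field")
    n_steps = int(round(length / DELTA))
    points, stages, truncated, _ = _grow(
        x0, y0, math.radians(angle_deg), n_steps, sens_for, field, rng, "main"
    )
    return AxonTrajectory(points, stages, neuron_id=neuron_id, truncated=truncated)


# ---------------------------------------------------------------------------
# fixed-point analysis


def _balance(y: float, sens: SensitivityVector, field: GrowthField) -> float:
    """Net dorso-ventral torque on a longitudinally heading tip at height y.

    Evaluated for the ascending heading (theta = pi) on the +y side; the
    descending case differs only by an overall sign, so the zero is shared.
    """
    m_d = field.dorsal_decay * LN10 * 10.0 ** (
        -field.dorsal_decay * (field.dv_halfwidth - y)
    )
    m_v = 0.0
    if y > field.ventral_source_offset:
        m_v = field.ventral_decay * LN10 * 10.0 ** (
            -field.ventral_decay * (y - field.ventral_source_offset)
        )
    # theta = pi, n = (0, -1): dorsal contributes -gamma_D*m_D, ventral +gamma_V*m_V
    return -sens.gamma_dorsal * m_d + sens.gamma_ventral * m_v


def fixed_point(sens: SensitivityVector, field: GrowthField) -> float:
    """Dorso-ventral height where the dorsal and ventral torques cancel.

    Found by bisection of the balance function on the marginal zone
    ``(floorplate_halfwidth, dv_halfwidth)``.  This is the height that
    longitudinal noise-free growth approaches asymptotically (when the
    balance is stable, i.e. both cues repulsive).  Raises
    :class:`NoFixedPointError` when the torques do not change sign in the
    interval (one-sided torque: growth pins at a barrier instead).
    """
    lo = field.floorplate_halfwidth + 1e-9
    hi = field.dv_halfwidth - 1e-9
    f_lo = _balance(lo, sens, field)
    f_hi = _balance(hi, sens, field)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise NoFixedPointError(
            "dorsal/ventral torques do not balance inside the marginal zone"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _balance(mid, sens, field)
        if f_mid == 0.0:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)
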