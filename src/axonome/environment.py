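"""The 2-D "opened-book" growth field of the tadpole hindbrain and spinal cord.

The roughly cylindrical CNS is cut along its dorsal midline and flattened, so
axons grow in a pair of rectangles (the two sides of the cord) joined at the
ventral floor plate.  The coordinate frame is:

* ``x`` — rostro-caudal position in µm, 0 at the midbrain–hindbrain border,
  increasing caudally (rostral = decreasing ``x``).
* ``y`` — signed dorso-ventral position in µm, ventral midline at 0; the two
  "pages" of the book are ``y > 0`` and ``y < 0``, so a floor-plate crossing
  is a continuous trajectory through ``y = 0``.

Guidance is provided by three line-source cues: an exponentially decaying
dorsal cue from the dorsal edge, an exponentially decaying ventral cue from
lines flanking the floor-plate midline, and a constant rostral polarity cue
signalling direction but not position.  Longitudinal barriers (rows of
tightly packed somata) deflect axons that contact them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

__all__ = [
    "GrowthField",
    "GradientCue",
    "Barrier",
    "OutOfFieldError",
    "cue_value",
    "cue_gradient",
    "apply_barriers",
    "barrier_hit",
    "default_field",
    "LN10",
]

LN10 = math.log(10.0)

#: Stage names, in the irreversible order they occur.
STAGES = ("outgrowth", "orientation", "main")

Side = Literal[-1, 1]


class OutOfFieldError(ValueError):
    """Raised when a point lies outside the growth field."""


@dataclass(frozen=True)
class GradientCue:
    """One guidance field: an exponential gradient or a constant polarity.

    ``decay`` is expressed as ``1/d`` where ``d`` is the distance (µm) over
    which the cue strength falls to 10% of its source value; the cue value at
    distance ``s`` from the source is ``10**(-decay * s)``.  ``decay = 0``
    marks a constant polarity cue whose value is 1 everywhere and which
    exposes a fixed direction instead of a spatial slope.
    """

    name: Literal["rostral", "dorsal", "ventral"]
    source: float  # edge coordinate in µm (|y| for DV cues, x for rostral)
    decay: float  # 1/µm; 0 => polarity cue

    def __post_init__(self) -> None:
        if self.decay < 0:
            raise ValueError("decay must be >= 0")


@dataclass(frozen=True)
class Barrier:
    """A longitudinal barrier at a fixed |y|, active over an rc range/stages.

    ``blocks`` restricts which approach direction is deflected:
    ``"dorsal-going"`` blocks movement toward larger |y|, ``"ventral-going"``
    toward smaller |y|, ``"both"`` blocks either.
    """

    dv_position: float  # µm from the ventral midline (unsigned)
    rc_range: tuple[float, float] = (0.0, math.inf)
    blocks: Literal["dorsal-going", "ventral-going", "both"] = "both"
    active_stages: frozenset[str] = frozenset(STAGES)

    def active(self, x: float, stage: str) -> bool:
        return self.rc_range[0] <= x <= self.rc_range[1] and stage in self.active_stages


@dataclass(frozen=True)
class GrowthField:
    """Rectangular opened-book growth environment with cues and barriers."""

    rc_extent: tuple[float, float] = (0.0, 2000.0)
    dv_halfwidth: float = 145.0
    floorplate_halfwidth: float = 25.0
    ventral_source_offset: float = 5.0  # ventral cue lines at |y| = 5 µm
    dorsal_decay: float = 1.0 / 50.0
    ventral_decay: float = 1.0 / 50.0
    barriers: tuple[Barrier, ...] = ()

    def __post_init__(self) -> None:
        if not self.rc_extent[0] < self.rc_extent[1]:
            raise ValueError("rc_extent must be a nonempty interval")
        if not 0 < self.floorplate_halfwidth < self.dv_halfwidth:
            raise ValueError("need 0 < floorplate_halfwidth < dv_halfwidth")
        for b in self.barriers:
            if not 0 <= b.dv_position <= self.dv_halfwidth:
                raise ValueError(f"barrier at {b.dv_position} outside [0, dv_halfwidth]")
            lo = max(b.rc_range[0], self.rc_extent[0])
            hi = min(b.rc_range[1], self.rc_extent[1])
            if lo > hi:
                raise ValueError(f"barrier rc_range {b.rc_range} outside field")

    # -- cue accessors -----------------------------------------------------
    @property
    def rostral_cue(self) -> GradientCue:
        return GradientCue("rostral", self.rc_extent[0], 0.0)

    @property
    def dorsal_cue(self) -> GradientCue:
        return GradientCue("dorsal", self.dv_halfwidth, self.dorsal_decay)

    @property
    def ventral_cue(self) -> GradientCue:
        return GradientCue("ventral", self.ventral_source_offset, self.ventral_decay)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.rc_extent[0] <= x <= self.rc_extent[1]
            and abs(y) <= self.dv_halfwidth
        )

    def nudge_off_barriers(self, y: float, eps: float = 0.5) -> float:
        """Move a soma placed exactly on a barrier line 0.5 µm off it."""
        for b in self.barriers:
            if abs(abs(y) - b.dv_position) < 1e-12:
                shift = -eps if b.dv_position > self.floorplate_halfwidth else eps
                return math.copysign(abs(y) + shift, y if y != 0 else 1.0)
        return y


def _cue_distance(cue: GradientCue, x: float, y: float) -> float:
    """Distance (µm) from a point to the cue's source line, on the point's side."""
    if cue.name == "rostral":
        return x - cue.source
    if cue.name == "dorsal":
        return cue.source - abs(y)
    # ventral: source lines at |y| = offset flanking the midline; inside the
    # flanked strip the cue is at its plateau (distance 0)
    return max(0.0, abs(y) - cue.source)


def cue_value(cue: GradientCue, x: float, y: float, field: GrowthField) -> float:
    """Cue concentration in (0, 1] at a point; 1 everywhere for a polarity cue."""
    if not field.contains(x, y):
        raise OutOfFieldError(f"point ({x}, {y}) outside the growth field")
    if cue.decay == 0.0:
        return 1.0
    return 10.0 ** (-cue.decay * _cue_distance(cue, x, y))


def cue_gradient(
    cue: GradientCue, x: float, y: float, field: GrowthField
) -> tuple[float, float]:
    """Spatial gradient of the cue at a point, as a 2-vector (per µm).

    Decaying cues return a vector pointing toward the source with magnitude
    ``value * decay * ln(10)`` (the analytic derivative of ``10**(-decay*s)``).
    The zero-slope rostral polarity cue instead returns its fixed direction
    (unit rostral, i.e. −x) scaled by the cue value.
    """
    v = cue_value(cue, x, y, field)
    if cue.name == "rostral":
        # polarity: direction only; magnitude = cue value (1.0)
        return (-v, 0.0)
    mag = v * cue.decay * LN10
    side = 1.0 if y >= 0 else -1.0
    if cue.name == "dorsal":
        return (0.0, side * mag)  # toward the dorsal edge on this side
    # ventral: toward the midline strip; zero slope on the plateau
    if abs(y) <= cue.source:
        return (0.0, 0.0)
    return (0.0, -side * mag)


# -- barriers --------------------------------------------------------------

def barrier_hit(
    prev_y: float,
    prop_y: float,
    x_at: float,
    stage: str,
    field: GrowthField,
) -> Barrier | None:
    """First active barrier strictly between |prev_y| and |prop_y|, if any.

    Barriers live at unsigned dorso-ventral positions and are mirrored on
    both sides; the test is on |y| so a floor-plate crossing (sign change
    within |y| < floorplate_halfwidth) does not register.  A segment that
    starts exactly on a barrier line and moves away is not a hit.
    """
    a, b = abs(prev_y), abs(prop_y)
    going_dorsal = b > a
    best: Barrier | None = None
    best_dist = math.inf
    for bar in field.barriers:
        if not bar.active(x_at, stage):
            continue
        if bar.blocks == "dorsal-going" and not going_dorsal:
            continue
        if bar.blocks == "ventral-going" and going_dorsal:
            continue
        lo, hi = min(a, b), max(a, b)
        if lo < bar.dv_position < hi or (b != a and bar.dv_position == b):
            d = abs(bar.dv_position - a)
            if d < best_dist:
                best, best_dist = bar, d
    return best


def apply_barriers(prev, proposed, field: GrowthField, rc_sign: int = 1):
    """Clamp a proposed step at the first barrier it crosses and turn it
    longitudinally.

    If the prev→proposed segment crosses a barrier that is active at the
    step's position and stage, the returned state lies on that segment at the
    barrier line, with heading set to the longitudinal direction whose sign
    matches the step's rostro-caudal component (ties broken toward the
    neuron's configured growth direction ``rc_sign``: +1 ascending/rostral,
    −1 descending/caudal).  Otherwise ``proposed`` is returned unchanged.
    """
    bar = barrier_hit(prev.y, proposed.y, prev.x, proposed.stage, field)
    if bar is None:
        return proposed
    a, b = abs(prev.y), abs(proposed.y)
    t = 0.0 if b == a else (bar.dv_position - a) / (b - a)
    t = min(max(t, 0.0), 1.0)
    cx = prev.x + t * (proposed.x - prev.x)
    cy = prev.y + t * (proposed.y - prev.y)
    dx = proposed.x - prev.x
    if dx > 0:
        theta = 0.0
    elif dx < 0:
        theta = math.pi
    else:
        theta = math.pi if rc_sign > 0 else 0.0
    return proposed.replace(x=cx, y=cy, theta=theta)


# -- default tadpole environment -------------------------------------------

def default_field(
    rc_length: float = 2000.0,
    dorsal_decay: float = 1.0 / 50.0,
    ventral_decay: float = 1.0 / 50.0,
    crossing_outgrowth: bool = True,
) -> GrowthField:
    """The standard tadpole hindbrain + rostral spinal cord field.

    Barriers (µm from the ventral midline): 25 (outer margin of the floor
    plate, ventral edge of the marginal zone, whole field); 125 and 127 (dli
    sensory-pathway soma column, which extends forward to x = 700 µm, so the
    barriers are active caudal of that); 137 (Rohon-Beard soma column,
    extending forward to x = 500 µm); 145 (dorsal limit of growth for the
    rostral part of the field, where the soma columns are absent).

    The 25 µm barrier is inactive during the outgrowth stage so commissural
    axons can enter and cross the floor plate.
    """
    fp_stages = frozenset({"orientation", "main"}) if crossing_outgrowth else frozenset(STAGES)
    barriers = (
        Barrier(25.0, (0.0, rc_length), "both", fp_stages),
        Barrier(125.0, (700.0, rc_length), "dorsal-going"),
        Barrier(127.0, (700.0, rc_length), "dorsal-going"),
        Barrier(137.0, (500.0, rc_length), "dorsal-going"),
        Barrier(145.0, (0.0, 500.0), "dorsal-going"),
    )
    return GrowthField(
        rc_extent=(0.0, rc_length),
        dorsal_decay=dorsal_decay,
        ventral_decay=ventral_decay,
        barriers=barriers,
    )
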