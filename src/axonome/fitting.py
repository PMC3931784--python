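"""Similarity metrics, the composite cost function, and pattern search.

The four main-stage growth parameters (rostral, dorsal and ventral
sensitivities and the noise half-width alpha) are fitted by minimising a
cost that compares a set of model-grown axons with a set of real (measured)
axons on two summary features:

* the **dorso-ventral histogram** — the distribution of |y| over points
  sampled at 1 µm arc-length intervals along all axons of a set, in 10 µm
  bins, as proportions; dissimilarity ``Q`` is the two-histogram chi-square
  distance ``sum (p_i - q_i)^2 / (p_i + q_i)`` over occupied bins;
* the **mean tortuosity** — arc length over chord length per axon, after
  resampling at 10 µm arc intervals so model and intermittently measured
  real axons are comparable.

The total cost is ``F = Q + kappa * (T_real - T_model)^2``.  Because model
axons are stochastic, F is a noisy objective; a derivative-free generalized
pattern search (mesh-based coordinate polling with expansion on success and
contraction on failure) is used to minimise it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .environment import GrowthField
from .growth import AxonTrajectory, SensitivityVector, grow_main_only
from .generalize import EmpiricalCDF, PairedSample, sample_1d, sample_2d

__all__ = [
    "DVHistogram",
    "CostBreakdown",
    "PatternSearchOptions",
    "ComparisonReport",
    "densify",
    "dv_histogram",
    "histogram_distance",
    "tortuosity",
    "mean_tortuosity",
    "CostEvaluator",
    "pattern_search",
    "compare_sets",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geometry helpers


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Points at ``step`` µm arc-length intervals, keeping the terminal point."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    total = arc[-1]
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-9:
        targets = np.r_[targets, total]
    else:
        targets[-1] = total
    xs = np.interp(targets, arc, pts[:, 0])
    ys = np.interp(targets, arc, pts[:, 1])
    return np.column_stack([xs, ys])


def densify(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Linearly interpolate a measured polyline to ``step`` µm spacing.

    Interpolation is per segment so every original vertex is retained;
    consecutive output points are ``step`` apart in arc length except for
    the (shorter) last sub-interval of each segment.  Duplicate consecutive
    input points are dropped with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need a polyline of >= 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        log.warning("dropping %d duplicate consecutive points", int((seg == 0).sum()))
        keep = np.r_[True, seg > 0]
        pts = pts[keep]
        seg = seg[seg > 0]
        if len(pts) < 2:
            raise ValueError("polyline degenerate after dropping duplicates")
    out = [pts[0]]
    for a, b, L in zip(pts[:-1], pts[1:], seg):
        n_full = int(math.floor(L / step - 1e-9))
        direction = (b - a) / L
        for i in range(1, n_full + 1):
            out.append(a + direction * (i * step))
        out.append(b)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# DV histogram


@dataclass(frozen=True)
class DVHistogram:
    """Proportions of densely sampled axon points per dorso-ventral bin."""

    bin_width: float
    edges: np.ndarray
    proportions: np.ndarray
    count: int

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def dv_histogram(
    point_sets: Sequence[np.ndarray],
    bin_width: float = 10.0,
    dv_halfwidth: float = 145.0,
) -> DVHistogram:
    """Pooled |y| histogram over a set of dense axon point lists.

    Bins of ``bin_width`` µm tile [0, dv_halfwidth] (the last bin absorbs
    the remainder when the halfwidth is not a multiple of the width).
    """
    if len(point_sets) == 0:
        raise ValueError("empty axon set")
    ys = np.abs(np.concatenate([np.asarray(p)[:, 1] for p in point_sets]))
    if len(ys) == 0:
        raise ValueError("axon set has no points")
    n_bins = int(math.ceil(dv_halfwidth / bin_width))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(ys, bins=edges)
    return DVHistogram(
        bin_width=bin_width,
        edges=edges,
        proportions=counts / counts.sum(),
        count=int(counts.sum()),
    )


def histogram_distance(h1: DVHistogram, h2: DVHistogram) -> float:
    """Chi-square distance ``sum (p-q)^2/(p+q)`` over occupied bins.

    Zero iff the proportion vectors are identical; symmetric; maximum 2 for
    histograms with disjoint support.
    """
    p, q = h1.proportions, h2.proportions
    if p.shape != q.shape:
        raise ValueError("histograms must share binning")
    s = p + q
    mask = s > 0
    return float(((p[mask] - q[mask]) ** 2 / s[mask]).sum())


# ---------------------------------------------------------------------------
# tortuosity


class ClosedLoopError(ValueError):
    """Chord length ~ 0: tortuosity undefined for a closed loop."""


def tortuosity(points: np.ndarray, resample_step: float = 10.0) -> float:
    """Arc/chord ratio of a polyline after 10 µm arc-length resampling.

    Resampling keeps the terminal point, so the chord (straight-line
    distance between the first and last points) is unchanged; a straight
    line therefore always has tortuosity exactly 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need a polyline of >= 2 points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-9:
        raise ClosedLoopError("chord length ~ 0 (closed loop)")
    rs = _resample_polyline(pts, resample_step)
    arc = float(np.linalg.norm(np.diff(rs, axis=0), axis=1).sum())
    return arc / chord


def mean_tortuosity(point_sets: Sequence[np.ndarray], resample_step: float = 10.0) -> float:
    """Mean tortuosity over a set, excluding (and logging) closed loops."""
    vals = []
    for i, pts in enumerate(point_sets):
        try:
            vals.append(tortuosity(pts, resample_step))
        except ClosedLoopError:
            log.info("axon %d excluded from tortuosity mean (closed loop)", i)
    if not vals:
        raise ValueError("no axon with a defined tortuosity")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# composite cost


@dataclass(frozen=True)
class CostBreakdown:
    """Auditable decomposition of one cost evaluation."""

    Q: float
    T_real: float
    T_model: float
    kappa: float
    F: float


@dataclass
class CostEvaluator:
    """Stochastic cost of a main-stage parameter vector against real axons.

    Each evaluation grows ``n_model_axons`` single-stage longitudinal model
    axons whose start position, initial angle and length are drawn by the
    generalization procedures from the real set's anatomy samples, then
    compares dorso-ventral histograms and mean tortuosities.  Every
    evaluation uses a fresh RNG substream derived from (seed, evaluation
    counter), so an optimization run is reproducible end to end while
    repeated evaluations at one parameter vector vary, as the noisy-cost
    optimizer requires.
    """

    real_axons: Sequence[np.ndarray]  # dense point lists
    length_cdf: EmpiricalCDF
    start_sample: PairedSample
    field: GrowthField
    rc_sign: int = 1
    n_model_axons: int = 50
    kappa: float = 1.0
    bin_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.real_axons) == 0:
            raise ValueError("real axon set is empty")
        self._real_hist = dv_histogram(
            self.real_axons, self.bin_width, self.field.dv_halfwidth
        )
        self._t_real = mean_tortuosity(self.real_axons)
        self._eval_count = 0

    def _start_x(self) -> float:
        # start at the caudal end for ascending growth, rostral for descending
        lo, hi = self.field.rc_extent
        return hi if self.rc_sign > 0 else lo

    def grow_model_set(
        self, params: SensitivityVector, rng: np.random.Generator
    ) -> list[AxonTrajectory]:
        """Main-stage model axons: generalized start height and length, with
        the longitudinal heading of the growth direction (the sampled
        outgrowth angle describes initial ventral outgrowth, which the main
        stage being fitted does not include)."""
        x0 = self._start_x()
        heading = 180.0 if self.rc_sign > 0 else 0.0
        axons = []
        for _ in range(self.n_model_axons):
            dv, _angle = sample_2d(self.start_sample, rng)
            length = sample_1d(self.length_cdf, float(rng.uniform()))
            axons.append(
                grow_main_only(
                    params, (x0, dv), heading, length, self.field, rng
                )
            )
        return axons

    def evaluate_with_model(self, model_pts: Sequence[np.ndarray]) -> CostBreakdown:
        """Cost breakdown against an explicit model point-set (F = 0 when the
        model set is the real set itself)."""
        if not model_pts:
            return CostBreakdown(math.inf, self._t_real, math.nan, self.kappa, math.inf)
        h_model = dv_histogram(model_pts, self.bin_width, self.field.dv_halfwidth)
        q = histogram_distance(self._real_hist, h_model)
        try:
            t_model = mean_tortuosity(model_pts)
        except ValueError:
            return CostBreakdown(math.inf, self._t_real, math.nan, self.kappa, math.inf)
        f = q + self.kappa * (self._t_real - t_model) ** 2
        return CostBreakdown(q, self._t_real, t_model, self.kappa, f)

    def __call__(self, x: np.ndarray) -> CostBreakdown:
        """Evaluate the cost at parameter vector (g_R, g_D, g_V, alpha)."""
        gr, gd, gv, alpha = (float(v) for v in x)
        self._eval_count += 1
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, self._eval_count])
        )
        if not all(map(math.isfinite, (gr, gd, gv, alpha))):
            return CostBreakdown(math.inf, self._t_real, math.nan, self.kappa, math.inf)
        params = SensitivityVector(gr, gd, gv, abs(alpha), self.rc_sign)
        model = self.grow_model_set(params, rng)
        return self.evaluate_with_model([t.points for t in model if len(t) >= 2])


# ---------------------------------------------------------------------------
# pattern search


@dataclass(frozen=True)
class PatternSearchOptions:
    initial_mesh: float = 0.5
    expansion: float = 2.0
    contraction: float = 0.5
    mesh_tolerance: float = 1e-3
    max_evaluations: int = 500
    #: re-evaluate the incumbent each poll round; for a noisy objective this
    #: counters the winner's curse of keeping one lucky draw forever
    refresh_incumbent: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.contraction < 1 < self.expansion:
            raise ValueError("need 0 < contraction < 1 < expansion")
        if self.mesh_tolerance <= 0:
            raise ValueError("mesh tolerance must be > 0")


@dataclass
class PatternSearchResult:
    x: np.ndarray
    F: float
    evaluations: int
    mesh: float
    progressed: bool
    trace: list  # (eval index, x, F, mesh) per accepted incumbent


def pattern_search(
    cost_fn: Callable[[np.ndarray], float],
    x0: np.ndarray,
    options: PatternSearchOptions = PatternSearchOptions(),
    rng: np.random.Generator | None = None,
    scale: np.ndarray | None = None,
) -> PatternSearchResult:
    """Generalized pattern search on a coordinate mesh of variable size.

    Polls the 2n coordinate directions (in random order when an ``rng`` is
    given) scaled by the current mesh size and an optional per-coordinate
    scale; the first improving poll becomes the incumbent and expands the
    mesh, a full unsuccessful poll contracts it.  Stops when the mesh falls
    below tolerance or the evaluation budget is exhausted.  Suits noisy
    objectives: no gradients are used and each comparison is a fresh
    evaluation.
    """
    x = np.asarray(x0, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("x0 must be finite")
    n = len(x)
    scale = np.ones(n) if scale is None else np.asarray(scale, dtype=float)
    mesh = options.initial_mesh
    f_x = float(_as_cost(cost_fn(x)))
    evals = 1
    progressed = False
    trace = [(evals, x.copy(), f_x, mesh)]
    directions = [(i, s) for i in range(n) for s in (+1.0, -1.0)]
    while mesh >= options.mesh_tolerance and evals < options.max_evaluations:
        if options.refresh_incumbent and evals > 1:
            f_x = float(_as_cost(cost_fn(x)))
            evals += 1
        order = list(range(len(directions)))
        if rng is not None:
            rng.shuffle(order)
        success = False
        for j in order:
            if evals >= options.max_evaluations:
                break
            i, s = directions[j]
            cand = x.copy()
            cand[i] += s * mesh * scale[i]
            f_c = float(_as_cost(cost_fn(cand)))
            evals += 1
            if f_c < f_x:
                x, f_x = cand, f_c
                mesh *= options.expansion
                success = True
                progressed = True
                trace.append((evals, x.copy(), f_x, mesh))
                break
        if not success:
            mesh *= options.contraction
    return PatternSearchResult(x=x, F=f_x, evaluations=evals, mesh=mesh,
                               progressed=progressed, trace=trace)


def _as_cost(value) -> float:
    return value.F if isinstance(value, CostBreakdown) else float(value)


# ---------------------------------------------------------------------------
# statistical comparison


@dataclass(frozen=True)
class ComparisonReport:
    """Two-sample comparison of model and real axon sets.

    The chi-square comparison of dorso-ventral histograms carries the caveat
    that successive points on one axon are not independent, so its p-value
    is indicative rather than exact.
    """

    t_statistic: float
    t_pvalue: float
    chi2_statistic: float
    chi2_pvalue: float
    caveat: str = (
        "histogram points are successive positions on the same axons and are "
        "not independent; the chi-square p-value is indicative only"
    )


def compare_sets(
    real_axons: Sequence[np.ndarray],
    model_axons: Sequence[np.ndarray],
    bin_width: float = 10.0,
    dv_halfwidth: float = 145.0,
) -> ComparisonReport:
    """Two-sample t-test on tortuosities and chi-square test on histograms."""
    if len(real_axons) < 2 or len(model_axons) < 2:
        raise ValueError("need >= 2 axons in each set")
    t_real = [tortuosity(a) for a in real_axons]
    t_model = [tortuosity(a) for a in model_axons]
    if np.allclose(t_real, np.mean(t_real)) and np.allclose(t_model, np.mean(t_model)) \
            and np.isclose(np.mean(t_real), np.mean(t_model)):
        t_stat, t_p = 0.0, 1.0  # identical degenerate sets
    else:
        t_stat, t_p = stats.ttest_ind(t_real, t_model, equal_var=False)
    h1 = dv_histogram(real_axons, bin_width, dv_halfwidth)
    h2 = dv_histogram(model_axons, bin_width, dv_halfwidth)
    # Two-sample chi-square on effective counts.  Successive 1 µm points on
    # one axon are strongly autocorrelated (each axon occupies a narrow DV
    # band), so raw point counts would make the test wildly anti-
    # conservative; one effectively independent observation per axon is used
    # instead, and the caveat is attached to the report.
    n1, n2 = float(len(real_axons)), float(len(model_axons))
    o1 = h1.proportions * n1
    o2 = h2.proportions * n2
    mask = (o1 + o2) > 0
    k1 = math.sqrt(n2 / n1)
    k2 = math.sqrt(n1 / n2)
    chi2 = float((((k1 * o1 - k2 * o2) ** 2)[mask] / (o1 + o2)[mask]).sum())
    dof = int(mask.sum()) - 1
    chi2_p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return ComparisonReport(float(t_stat), float(t_p), chi2, chi2_p)
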