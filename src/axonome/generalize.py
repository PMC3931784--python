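"""Generating unlimited values distributionally matched to small samples.

Anatomical measurements (axon lengths, start positions, branch geometry,
dendrite extents) come in samples of a few dozen cases.  Two procedures turn
such a sample into an unlimited supply of realistic values:

* **1-D inverse-ECDF sampling** — a piecewise-linear approximation of the
  sample's cumulative distribution function is inverted at a uniform random
  probability ``w``, so generated values interpolate between the observed
  ones and stay inside the observed range.
* **2-D smoothed bootstrap** — for ordered pairs (e.g. dorso-ventral start
  position and outgrowth angle, which co-vary), a measured pair is drawn
  uniformly and jittered with independent per-dimension Gaussian kernels,
  with rejection to stay inside optional bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmpiricalCDF",
    "PairedSample",
    "RejectionError",
    "fit_ecdf",
    "sample_1d",
    "sample_2d",
    "silverman_bandwidth",
]

_REJECTION_CAP = 1000


class RejectionError(RuntimeError):
    """Bounds exclude essentially all kernel mass (rejection cap exceeded)."""


@dataclass(frozen=True)
class EmpiricalCDF:
    """Piecewise-linear CDF knots fitted to a 1-D sample.

    Knot convention: plotting positions (i-1)/(k-1) for the i-th of k sorted
    values, so ``w = 0`` and ``w = 1`` map exactly to the sample extremes
    and every intermediate ``w`` interpolates strictly between neighbouring
    observations (no probability atom at the minimum).
    """

    values: np.ndarray  # non-decreasing knot abscissae
    probs: np.ndarray  # strictly increasing, probs[0] >= 0, probs[-1] == 1

    def __post_init__(self) -> None:
        v, p = np.asarray(self.values), np.asarray(self.probs)
        if v.shape != p.shape or v.ndim != 1 or len(v) < 1:
            raise ValueError("knots must be parallel 1-D arrays")
        if np.any(np.diff(v) < 0) or np.any(np.diff(p) <= 0):
            raise ValueError("values must be non-decreasing, probs strictly increasing")
        if abs(p[-1] - 1.0) > 1e-12:
            raise ValueError("last knot probability must be 1")

    @property
    def degenerate(self) -> bool:
        return len(self.values) == 1 or self.values[0] == self.values[-1]


@dataclass(frozen=True)
class PairedSample:
    """A small sample of measured 2-tuples with smoothing bandwidths."""

    points: np.ndarray  # (k, 2)
    bandwidth: tuple[float, float] | None = None  # per-dimension kernel SD
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("need >= 2 measured 2-tuples")
        object.__setattr__(self, "points", pts)
        bw = self.bandwidth
        if bw is None:
            bw = silverman_bandwidth(pts)
            object.__setattr__(self, "bandwidth", bw)
        if not all(b > 0 for b in bw):
            raise ValueError("bandwidths must be > 0")


def silverman_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-dimension Silverman rule-of-thumb kernel SD for a 2-column sample."""
    pts = np.asarray(points, dtype=float)
    k = len(pts)
    out = []
    for d in range(2):
        col = pts[:, d]
        sd = float(np.std(col, ddof=1))
        q75, q25 = np.percentile(col, [75, 25])
        iqr = (q75 - q25) / 1.34
        scale = min(sd, iqr) if iqr > 0 else sd
        if scale <= 0:
            scale = max(abs(col).max(), 1.0) * 1e-3  # degenerate column
        out.append(0.9 * scale * k ** (-0.2))
    return (out[0], out[1])


def fit_ecdf(sample) -> EmpiricalCDF:
    """Fit the piecewise-linear empirical CDF of a 1-D sample.

    Ties are collapsed to a single knot at the shared value (carrying the
    highest of the tied cumulative probabilities).  An all-identical sample
    yields a degenerate CDF mapping every ``w`` to that value.
    """
    vals = np.sort(np.asarray(sample, dtype=float))
    if vals.ndim != 1 or len(vals) < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    if not np.all(np.isfinite(vals)):
        raise ValueError("sample values must be finite")
    k = len(vals)
    if vals[0] == vals[-1]:
        # all values identical: degenerate CDF
        return EmpiricalCDF(values=vals[-1:], probs=np.array([1.0]))
    probs = np.arange(k) / (k - 1)
    # collapse ties: keep the last occurrence of each value
    keep = np.r_[vals[1:] != vals[:-1], True]
    return EmpiricalCDF(values=vals[keep], probs=probs[keep])


def sample_1d(cdf: EmpiricalCDF, w: float) -> float:
    """Invert the piecewise-linear CDF at probability ``w`` in [0, 1].

    Deterministic given ``(cdf, w)``; ``w = 0`` maps to the sample minimum
    and ``w = 1`` to the maximum.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if cdf.degenerate:
        return float(cdf.values[0])
    # np.interp clips below the first knot, which handles a tied minimum
    return float(np.interp(w, cdf.probs, cdf.values))


def sample_2d(sample: PairedSample, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one smoothed-bootstrap pair from a 2-D sample.

    Picks a measured pair uniformly at random, jitters each component with
    independent Gaussian noise at the per-dimension bandwidth, and redraws
    until the result falls inside the bounds (if any).
    """
    pts, (h0, h1) = sample.points, sample.bandwidth
    for _ in range(_REJECTION_CAP):
        base = pts[rng.integers(len(pts))]
        out0 = base[0] + rng.normal(0.0, h0)
        out1 = base[1] + rng.normal(0.0, h1)
        if sample.bounds is not None:
            (lo0, hi0), (lo1, hi1) = sample.bounds
            if not (lo0 <= out0 <= hi0 and lo1 <= out1 <= hi1):
                continue
        return float(out0), float(out1)
    raise RejectionError(
        f"no in-bounds draw after {_REJECTION_CAP} attempts; "
        "bounds exclude essentially all kernel mass"
    )
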