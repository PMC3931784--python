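"""Synthetic anatomical samples standing in for measured tadpole datasets.

The measured axon-length, start-position/outgrowth-angle, branch and
dendrite samples this model generalizes from are not publicly deposited.
This module generates synthetic samples with the same structure — unimodal
length distributions inside the published ranges, correlated 2-D
start/angle clouds, Gaussian dendrite extents — so every stage of the
pipeline runs self-contained.  The samples are structurally realistic
stand-ins, not statistical imitations of the real data beyond the printed
ranges and counts (the published cIN length sample: k = 46 values in
110–1450 µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .environment import GrowthField
from .growth import AxonTrajectory, SensitivityVector, grow_main_only
from .generalize import EmpiricalCDF, PairedSample, fit_ecdf, sample_1d, sample_2d

__all__ = [
    "TypeFixtureSpec",
    "FixtureSpec",
    "default_fixture_spec",
    "make_anatomy_samples",
    "write_anatomy_samples",
    "make_reference_axons",
]


@dataclass(frozen=True)
class TypeFixtureSpec:
    """Shape of the synthetic anatomy for one neuron type."""

    name: str
    # axon lengths: truncated log-normal inside a hard range
    length_count: int
    length_range: tuple[float, float]
    length_logmean: float
    length_logsd: float
    # (dv start, outgrowth angle °) cloud: 2-D Gaussian
    start_count: int
    start_mean: tuple[float, float]
    start_sd: tuple[float, float]
    start_corr: float
    start_bounds: tuple[tuple[float, float], tuple[float, float]]
    # branch geometry (1-D samples)
    branch_distance_count: int
    branch_distance_range: tuple[float, float]
    branch_angle_count: int
    branch_angle_mean: float
    branch_angle_sd: float
    # dendrite bars: (d_low, extent) Gaussians, clipped into the marginal zone
    dendrite_count: int
    dendrite_low_mean: float
    dendrite_low_sd: float
    dendrite_extent_mean: float
    dendrite_extent_sd: float
    dendrite_bounds: tuple[float, float] = (25.0, 145.0)


@dataclass(frozen=True)
class FixtureSpec:
    types: tuple[TypeFixtureSpec, ...]
    seed: int = 0


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Demo anatomy for the two worked neuron types.

    The cIN-like length sample matches the published size and range (k = 46,
    110–1450 µm); the remaining shapes are realistic choices for ~100 µm
    dorso-ventral marginal zones: ventrally directed outgrowth angles around
    −90° (on the +y side) correlated with dorso-ventral start position, and
    dendrite bars a few tens of µm tall.
    """
    ain = TypeFixtureSpec(
        name="aIN-like",
        length_count=30,
        length_range=(150.0, 1200.0),
        length_logmean=6.2,
        length_logsd=0.5,
        start_count=24,
        start_mean=(60.0, -80.0),
        start_sd=(18.0, 25.0),
        start_corr=0.4,
        start_bounds=((25.0, 145.0), (-170.0, -10.0)),
        branch_distance_count=20,
        branch_distance_range=(0.0, 250.0),
        branch_angle_count=20,
        branch_angle_mean=0.0,
        branch_angle_sd=25.0,
        dendrite_count=25,
        dendrite_low_mean=45.0,
        dendrite_low_sd=12.0,
        dendrite_extent_mean=35.0,
        dendrite_extent_sd=15.0,
    )
    cin = TypeFixtureSpec(
        name="cIN-like",
        length_count=46,
        length_range=(110.0, 1450.0),
        length_logmean=6.3,
        length_logsd=0.6,
        start_count=33,
        start_mean=(65.0, -90.0),
        start_sd=(20.0, 20.0),
        start_corr=0.3,
        start_bounds=((25.0, 145.0), (-170.0, -10.0)),
        branch_distance_count=22,
        branch_distance_range=(0.0, 300.0),
        branch_angle_count=22,
        branch_angle_mean=0.0,
        branch_angle_sd=25.0,
        dendrite_count=28,
        dendrite_low_mean=50.0,
        dendrite_low_sd=12.0,
        dendrite_extent_mean=40.0,
        dendrite_extent_sd=15.0,
    )
    return FixtureSpec(types=(ain, cin), seed=seed)


def _truncated_lognormal(
    rng: np.random.Generator, n: int, logmean: float, logsd: float,
    lo: float, hi: float,
) -> np.ndarray:
    out = np.empty(n)
    i = 0
    while i < n:
        v = float(rng.lognormal(logmean, logsd))
        if lo <= v <= hi:
            out[i] = v
            i += 1
    return out


def make_anatomy_samples(spec: FixtureSpec) -> dict[str, dict[str, np.ndarray]]:
    """Generate per-type anatomy sample arrays, reproducible from the spec.

    Returns ``{type name: {"lengths", "start_dv_angle", "branch_distance",
    "branch_angle", "dendrite_extent"}}`` with 1- or 2-column arrays in the
    dialects the generalization module reads.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for t in spec.types:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, _stable_hash(t.name)])
        )
        lengths = _truncated_lognormal(
            rng, t.length_count, t.length_logmean, t.length_logsd, *t.length_range
        )
        cov = np.array(
            [
                [t.start_sd[0] ** 2, t.start_corr * t.start_sd[0] * t.start_sd[1]],
                [t.start_corr * t.start_sd[0] * t.start_sd[1], t.start_sd[1] ** 2],
            ]
        )
        starts = np.empty((t.start_count, 2))
        (b0, b1) = t.start_bounds
        i = 0
        while i < t.start_count:
            p = rng.multivariate_normal(t.start_mean, cov)
            if b0[0] <= p[0] <= b0[1] and b1[0] <= p[1] <= b1[1]:
                starts[i] = p
                i += 1
        branch_d = rng.uniform(*t.branch_distance_range, t.branch_distance_count)
        branch_a = rng.normal(t.branch_angle_mean, t.branch_angle_sd, t.branch_angle_count)
        lo_b, hi_b = t.dendrite_bounds
        d_low = np.clip(
            rng.normal(t.dendrite_low_mean, t.dendrite_low_sd, t.dendrite_count),
            lo_b, hi_b,
        )
        ext = np.abs(rng.normal(t.dendrite_extent_mean, t.dendrite_extent_sd, t.dendrite_count))
        d_high = np.clip(d_low + ext, lo_b, hi_b)
        out[t.name] = {
            "lengths": lengths,
            "start_dv_angle": starts,
            "branch_distance": branch_d,
            "branch_angle": branch_a,
            "dendrite_extent": np.column_stack([d_low, d_high]),
        }
    return out


_COLUMNS = {
    "lengths": ["length_um"],
    "start_dv_angle": ["dv_um", "angle_deg"],
    "branch_distance": ["distance_um"],
    "branch_angle": ["angle_deg"],
    "dendrite_extent": ["d_low_um", "d_high_um"],
}


def write_anatomy_samples(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write the fixture anatomy as the CSV files the pipeline consumes.

    File naming: ``<type>__<sample>.csv`` with a header naming the quantity
    and units.  Output is byte-identical for a fixed spec (values printed at
    fixed precision).
    """
    import csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = make_anatomy_samples(spec)
    written = []
    for type_name, tables in samples.items():
        for sample_name, arr in tables.items():
            path = out_dir / f"{type_name}__{sample_name}.csv"
            arr2 = np.atleast_2d(arr.T).T  # 1-D -> column
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(_COLUMNS[sample_name])
                for row in arr2:
                    w.writerow([f"{v:.6f}" for v in np.atleast_1d(row)])
            written.append(path)
    return written


def make_reference_axons(
    true_params: SensitivityVector,
    n: int,
    length_cdf: EmpiricalCDF,
    start_sample: PairedSample,
    field: GrowthField,
    rng: np.random.Generator,
    start_x: float | None = None,
    longitudinal_angle: bool = True,
) -> list[AxonTrajectory]:
    """Grow a reference set of main-stage axons at known parameters.

    Used as the "real axon" surrogate in optimization tests: the generating
    parameters are known, so recovery can be scored.  Axons start at the
    caudal (ascending) or rostral (descending) end of the field, at
    generalized dorso-ventral positions and lengths; when
    ``longitudinal_angle`` is set the initial heading is longitudinal (the
    main stage is being emulated), otherwise the generalized outgrowth angle
    is used.
    """
    if start_x is None:
        start_x = field.rc_extent[1] if true_params.rc_sign > 0 else field.rc_extent[0]
    axons = []
    for _ in range(n):
        dv, angle = sample_2d(start_sample, rng)
        if longitudinal_angle:
            angle = 180.0 if true_params.rc_sign > 0 else 0.0
        length = sample_1d(length_cdf, float(rng.uniform()))
        axons.append(
            grow_main_only(true_params, (start_x, dv), angle, length, field, rng)
        )
    return axons


def _stable_hash(name: str) -> int:
    """Deterministic 31-bit hash of a name (Python's hash() is salted)."""
    h = 2166136261
    for b in name.encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h & 0x7FFFFFFF
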