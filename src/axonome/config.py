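"""Structured run configuration, neuron-type profiles and seed management.

A run is fully described by one YAML file with four sections —
``environment``, ``types``, ``population`` and ``fitting`` — plus a master
seed.  The loader validates the schema before any computation and rejects
unknown keys with their location.  One master seed spawns named substreams
(soma placement, per-neuron growth, synapse formation, per-evaluation
fitting) so a change in one subsystem does not perturb another's draws.

The shipped default profiles describe the two worked neuron types:

* ``aIN-like`` — uncrossed ascending primary axon with a descending
  secondary; brief ventral outgrowth, orientation to rostral growth, then a
  main stage held mid-marginal-zone by repulsion from both the dorsal and
  ventral cue sources.
* ``cIN-like`` — commissural: ventral outgrowth through the floor plate,
  orientation on the opposite side with the ventral sensitivity sign
  reversed (attraction before crossing, repulsion after), then ascending
  main growth and a descending secondary.

The per-stage sensitivity magnitudes are model calibration constants chosen
to satisfy the qualitative growth behaviour (stable interior dorso-ventral
balance, reliable floor-plate crossing, realistic wiggliness); the shared
environment (gradient edges, 10%-decay distances, barrier rows) follows the
published tadpole geometry.
"""

from __future__ import annotations

import copy
import csv
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .environment import GrowthField, default_field
from .generalize import PairedSample, fit_ecdf
from .growth import (
    AnatomySamples,
    NeuronTypeSpec,
    OrientationTrigger,
    SensitivitySchedule,
    SensitivityVector,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "stable_hash",
    "spawn_rng",
    "default_config",
    "load_config",
    "build_field",
    "build_type_spec",
    "load_anatomy",
    "config_hash",
]


# ---------------------------------------------------------------------------
# seeding


def stable_hash(name: str) -> int:
    """Deterministic 31-bit FNV-1a hash of a name (hash() is salted)."""
    h = 2166136261
    for b in name.encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h & 0x7FFFFFFF


def spawn_rng(seed: int, *names: str | int) -> np.random.Generator:
    """A named, reproducible substream of the master seed."""
    keys = [seed & 0x7FFFFFFF]
    for n in names:
        keys.append(stable_hash(n) if isinstance(n, str) else int(n) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


# ---------------------------------------------------------------------------
# schema


class ConfigError(ValueError):
    """A configuration file violated the schema; the message carries the key path."""


_SENS_KEYS = {"gamma_rostral", "gamma_dorsal", "gamma_ventral", "alpha", "rc_sign"}

_DEFAULT: dict = {
    "seed": 0,
    "environment": {
        "rc_length": 2000.0,
        "dorsal_decay_distance": 50.0,  # µm over which the cue falls to 10%
        "ventral_decay_distance": 50.0,
    },
    "types": {
        "aIN-like": {
            "crossing": False,
            "primary_direction": "ascending",
            "synapse_class": "non-sensory",
            "has_secondary": True,
            "orientation_trigger": {"kind": "longitudinal_offset", "value": 5.0},
            "outgrowth": {
                "gamma_rostral": 0.1,
                "gamma_dorsal": 0.0,
                "gamma_ventral": 0.5,
                "alpha": 0.1,
            },
            "orientation_start": {
                "gamma_rostral": 1.5,
                "gamma_dorsal": -1.0,
                "gamma_ventral": -1.0,
            },
            "main": {
                "gamma_rostral": 0.05,
                "gamma_dorsal": -4.0,
                "gamma_ventral": -4.0,
                "alpha": 0.2,
            },
            "orientation_decay_rates": [0.05, 0.05, 0.05],
            "secondary": None,  # null -> reuse the main-stage parameters
        },
        "cIN-like": {
            "crossing": True,
            "primary_direction": "ascending",
            "synapse_class": "non-sensory",
            "has_secondary": True,
            "orientation_trigger": {"kind": "floorplate_exit", "value": 0.0},
            "outgrowth": {
                "gamma_rostral": 0.005,
                "gamma_dorsal": 0.0,
                "gamma_ventral": 1.5,
                "alpha": 0.02,
            },
            "orientation_start": {
                "gamma_rostral": 1.5,
                "gamma_dorsal": -0.5,
                "gamma_ventral": -3.0,
            },
            "main": {
                "gamma_rostral": 0.05,
                "gamma_dorsal": -4.0,
                "gamma_ventral": -4.0,
                "alpha": 0.2,
            },
            "orientation_decay_rates": [0.05, 0.05, 0.05],
            "secondary": None,
        },
    },
    "population": {
        # the worked two-type example: counts on one side of the cord
        "aIN-like": {"count": 68, "rc_range": [300.0, 2000.0], "side": 1},
        "cIN-like": {"count": 192, "rc_range": [300.0, 2000.0], "side": 1},
    },
    "synapses": {"p_default": 0.46, "p_sensory": 0.63, "min_separation": 1.5},
    "fitting": {
        "kappa": 300.0,
        "bin_width": 10.0,
        "n_model_axons": 50,
        "initial_mesh": 0.5,
        "expansion": 2.0,
        "contraction": 0.5,
        "mesh_tolerance": 1e-3,
        "max_evaluations": 500,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT)


def _check_keys(data: dict, ref: dict, path: str, open_sections: set[str]) -> None:
    for key, val in data.items():
        here = f"{path}.{key}" if path else key
        if path in open_sections:
            continue
        if key not in ref:
            raise ConfigError(f"unknown key {here!r} (known: {sorted(ref)})")
        if isinstance(val, dict) and isinstance(ref[key], dict):
            _check_keys(val, ref[key], here, open_sections)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated configuration plus derived model objects."""

    data: dict

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def field(self) -> GrowthField:
        return build_field(self.data)

    def type_names(self) -> list[str]:
        return list(self.data["types"])


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load, merge with defaults, and validate a YAML configuration.

    Unknown keys are rejected with their dotted location.  ``types`` and
    ``population`` accept user-defined type names; within each type the
    parameter keys are still schema-checked.
    """
    data = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        _validate_user(user)
        data = _merge(data, user)
    if overrides:
        data = _merge(data, overrides)
    _validate_full(data)
    return RunConfig(data)


def _validate_user(user: dict) -> None:
    top = set(_DEFAULT)
    for key in user:
        if key not in top:
            raise ConfigError(f"unknown key {key!r} (known: {sorted(top)})")
    ref_type = _DEFAULT["types"]["aIN-like"]
    for tname, tdata in (user.get("types") or {}).items():
        if not isinstance(tdata, dict):
            raise ConfigError(f"types.{tname}: must be a mapping")
        _check_keys(tdata, ref_type, f"types.{tname}", set())
    for pname, pdata in (user.get("population") or {}).items():
        if not isinstance(pdata, dict):
            raise ConfigError(f"population.{pname}: must be a mapping")
        _check_keys(pdata, {"count": 0, "rc_range": [], "side": 1},
                    f"population.{pname}", set())
    for section in ("environment", "synapses", "fitting"):
        if section in user:
            _check_keys(user[section], _DEFAULT[section], section, set())


def _validate_full(data: dict) -> None:
    env = data["environment"]
    if env["rc_length"] <= 0:
        raise ConfigError("environment.rc_length must be > 0")
    for k in ("dorsal_decay_distance", "ventral_decay_distance"):
        if env[k] <= 0:
            raise ConfigError(f"environment.{k} must be > 0")
    syn = data["synapses"]
    for k in ("p_default", "p_sensory"):
        if not 0 <= syn[k] <= 1:
            raise ConfigError(f"synapses.{k} must lie in [0, 1]")
    for pname, p in data["population"].items():
        if pname not in data["types"]:
            raise ConfigError(
                f"population.{pname}: no such type (known: {sorted(data['types'])})"
            )
        if p["count"] < 0:
            raise ConfigError(f"population.{pname}.count must be >= 0")


def build_field(data: dict) -> GrowthField:
    env = data["environment"]
    return default_field(
        rc_length=float(env["rc_length"]),
        dorsal_decay=1.0 / float(env["dorsal_decay_distance"]),
        ventral_decay=1.0 / float(env["ventral_decay_distance"]),
    )


def _sens(d: dict, fallback_alpha: float = 0.0, rc_sign: int = 1) -> SensitivityVector:
    return SensitivityVector(
        gamma_rostral=float(d.get("gamma_rostral", 0.0)),
        gamma_dorsal=float(d.get("gamma_dorsal", 0.0)),
        gamma_ventral=float(d.get("gamma_ventral", 0.0)),
        alpha=float(d.get("alpha", fallback_alpha)),
        rc_sign=int(d.get("rc_sign", rc_sign)),
    )


def build_type_spec(
    data: dict, name: str, samples: AnatomySamples | None = None
) -> NeuronTypeSpec:
    """Materialise one neuron type's profile as a NeuronTypeSpec."""
    try:
        t = data["types"][name]
    except KeyError:
        raise ConfigError(
            f"unknown type {name!r} (known: {sorted(data['types'])})"
        ) from None
    rc_sign = 1 if t["primary_direction"] == "ascending" else -1
    main = _sens(t["main"], rc_sign=rc_sign)
    start = _sens(t["orientation_start"], fallback_alpha=main.alpha, rc_sign=rc_sign)
    sec = t.get("secondary")
    trig = t["orientation_trigger"]
    return NeuronTypeSpec(
        name=name,
        crossing=bool(t["crossing"]),
        primary_direction=t["primary_direction"],
        outgrowth_params=_sens(t["outgrowth"], rc_sign=rc_sign),
        schedule=SensitivitySchedule(
            start=start,
            main=main,
            decay_rates=tuple(float(r) for r in t["orientation_decay_rates"]),
        ),
        secondary_params=None if sec is None else _sens(sec, rc_sign=rc_sign),
        orientation_trigger=OrientationTrigger(trig["kind"], float(trig["value"])),
        samples=samples,
        population=int(data["population"].get(name, {}).get("count", 0)),
        synapse_class=t["synapse_class"],
        has_secondary=bool(t["has_secondary"]),
    )


# ---------------------------------------------------------------------------
# anatomy sample files


def _read_csv(path: Path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise ConfigError(f"{path}: no data rows")
    try:
        arr = np.asarray([[float(v) for v in r] for r in rows[1:]])
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from None
    return arr[:, 0] if arr.shape[1] == 1 else arr


def load_anatomy(samples_dir: str | Path, type_name: str,
                 dv_bounds: tuple[float, float] = (25.0, 145.0)) -> AnatomySamples:
    """Read one type's anatomy CSVs (the dialect the fixtures module writes).

    The start cloud is bounded to the marginal zone's dorso-ventral range;
    generalized draws are rejected outside it.
    """
    d = Path(samples_dir)

    def need(sample: str) -> np.ndarray:
        path = d / f"{type_name}__{sample}.csv"
        if not path.exists():
            raise ConfigError(f"missing anatomy sample file: {path}")
        return _read_csv(path)

    def optional(sample: str) -> np.ndarray | None:
        path = d / f"{type_name}__{sample}.csv"
        return _read_csv(path) if path.exists() else None

    starts = need("start_dv_angle")
    dendr = optional("dendrite_extent")
    return AnatomySamples(
        lengths=need("lengths"),
        start_dv_angle=PairedSample(
            points=starts, bounds=(dv_bounds, (-360.0, 360.0))
        ),
        branch_distance=optional("branch_distance"),
        branch_angle=optional("branch_angle"),
        dendrite_extent=None if dendr is None else PairedSample(points=dendr),
    )


def config_hash(data: dict) -> str:
    """Stable short hash of a configuration for provenance records."""
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
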