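"""Assembling a connectome: somata, dendrites, axons, probabilistic synapses.

Network assembly runs in the order development does: neuron somata are
placed along the rostro-caudal axis (consecutively by type, with a minimum
longitudinal separation between all individuals), each soma receives a
dorso-ventral position and axon outgrowth angle from the 2-D generalization
procedure, dendrites are laid down as vertical bars at the soma's
rostro-caudal position, axons are grown with the stage machine, and finally
a synapse forms independently at each geometric axon–dendrite meeting with a
measured probability (0.46 for most connections, 0.63 for sensory-pathway
connections).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .environment import GrowthField
from .growth import AxonTrajectory, NeuronTypeSpec
from .generalize import PairedSample, sample_2d

__all__ = [
    "Neuron",
    "Synapse",
    "Connectome",
    "PackingError",
    "P_DEFAULT",
    "P_SENSORY",
    "MIN_SEPARATION",
    "place_somata",
    "assign_soma_dv_and_angle",
    "assign_dendrite",
    "find_meetings",
    "form_synapses",
    "export_connectome",
    "read_edge_list",
]

#: Measured probability that an axon-dendrite meeting forms a synapse.
P_DEFAULT = 0.46
#: Measured probability for sensory-pathway connections.
P_SENSORY = 0.63
#: Minimum longitudinal separation between any two somata, µm.
MIN_SEPARATION = 1.5

_PLACEMENT_CAP = 10_000  # rejection redraws per soma before giving up


class PackingError(RuntimeError):
    """Soma placement could not satisfy the minimum separation."""


@dataclass
class Neuron:
    id: str
    type_name: str
    soma: tuple[float, float]  # (x, y); side = sign(y)
    dendrite: tuple[float, float] | None = None  # (d_low, d_high), unsigned DV
    axons: list[AxonTrajectory] = dc_field(default_factory=list)
    synapse_class: str = "non-sensory"

    @property
    def side(self) -> int:
        return 1 if self.soma[1] >= 0 else -1


@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    location: tuple[float, float]  # (x, y)
    meeting_index: int  # which crossing of this axon-dendrite pair


@dataclass
class Connectome:
    neurons: list[Neuron]
    synapses: list[Synapse]
    provenance: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# placement


def place_somata(
    pop_specs: Sequence[tuple[str, int, tuple[float, float]]],
    field: GrowthField,
    rng: np.random.Generator,
    min_sep: float = MIN_SEPARATION,
) -> list[tuple[str, float]]:
    """Place somata longitudinally, consecutively by type.

    ``pop_specs`` is a list of ``(type name, count, rc range)``; each soma's
    x is drawn uniformly from its type's rc range and redrawn until it is at
    least ``min_sep`` from every previously placed soma (all types pooled).
    """
    total = sum(c for _, c, _ in pop_specs)
    lo, hi = field.rc_extent
    if total * min_sep >= hi - lo:
        raise PackingError(
            f"{total} somata at {min_sep} µm separation cannot fit in "
            f"{hi - lo} µm"
        )
    placed: list[tuple[str, float]] = []
    xs = np.empty(0)
    for type_name, count, rc_range in pop_specs:
        a, b = rc_range
        for i in range(count):
            for _ in range(_PLACEMENT_CAP):
                x = float(rng.uniform(a, b))
                if len(xs) == 0 or np.abs(xs - x).min() >= min_sep:
                    placed.append((type_name, x))
                    xs = np.append(xs, x)
                    break
            else:
                raise PackingError(
                    f"could not place soma {i + 1}/{count} of type "
                    f"{type_name!r} after {_PLACEMENT_CAP} draws"
                )
    return placed


def assign_soma_dv_and_angle(
    type_sample: PairedSample, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw a (dorso-ventral position, outgrowth angle °) pair for one soma."""
    return sample_2d(type_sample, rng)


def assign_dendrite(
    type_sample: PairedSample,
    rng: np.random.Generator,
    dv_halfwidth: float = 145.0,
) -> tuple[float, float]:
    """Draw a dendrite bar (d_low, d_high); swap-and-clip keeps it valid."""
    d_low, d_high = sample_2d(type_sample, rng)
    if d_low > d_high:
        d_low, d_high = d_high, d_low
    d_low = min(max(d_low, 0.0), dv_halfwidth)
    d_high = min(max(d_high, 0.0), dv_halfwidth)
    return d_low, d_high


# ---------------------------------------------------------------------------
# meetings and synapses


def find_meetings(
    axon: AxonTrajectory,
    post: Neuron,
    floorplate_halfwidth: float = 25.0,
    crossing_axon: bool = False,
) -> list[tuple[float, float]]:
    """Locations where an axon crosses the post neuron's dendrite bar.

    A segment yields a meeting when its rostro-caudal interval brackets the
    post soma's x (half-open, so a traversal touching the bar's x at a shared
    vertex counts once), the interpolated y at that x lies within the bar's
    dorso-ventral extent, and the segment is on the dendrite's side.  The
    outgrowth-stage portion of a commissural axon inside the floor plate
    forms no meetings (no dendrites there).
    """
    if post.dendrite is None:
        return []
    sx = post.soma[0]
    d_low, d_high = post.dendrite
    side = post.side
    pts = axon.points
    out: list[tuple[float, float]] = []
    x0s, y0s = pts[:-1, 0], pts[:-1, 1]
    x1s, y1s = pts[1:, 0], pts[1:, 1]
    lo = np.minimum(x0s, x1s)
    hi = np.maximum(x0s, x1s)
    cand = np.nonzero((lo <= sx) & (sx < hi))[0]
    for i in cand:
        x0, y0, x1, y1 = x0s[i], y0s[i], x1s[i], y1s[i]
        t = (sx - x0) / (x1 - x0)
        y_at = y0 + t * (y1 - y0)
        if (1 if y_at >= 0 else -1) != side:
            continue
        if not d_low <= abs(y_at) <= d_high:
            continue
        if (
            crossing_axon
            and axon.stages[i] == "outgrowth"
            and abs(y_at) < floorplate_halfwidth
        ):
            continue
        out.append((float(sx), float(y_at)))
    return out


def form_synapses(
    neurons: Sequence[Neuron],
    rng: np.random.Generator,
    p_default: float = P_DEFAULT,
    p_sensory: float = P_SENSORY,
    field: GrowthField | None = None,
    type_specs: dict[str, NeuronTypeSpec] | None = None,
) -> Connectome:
    """Bernoulli synapse formation at every axon-dendrite meeting.

    The probability class is chosen by the presynaptic neuron's synapse
    class; self-synapses are never formed.  Meetings are enumerated in a
    fixed neuron order so the result is reproducible from the rng state.
    """
    if not 0 <= p_default <= 1 or not 0 <= p_sensory <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    fp = field.floorplate_halfwidth if field is not None else 25.0
    synapses: list[Synapse] = []
    for pre in neurons:
        p = p_sensory if pre.synapse_class == "sensory" else p_default
        crossing = bool(
            type_specs and pre.type_name in type_specs
            and type_specs[pre.type_name].crossing
        )
        for axon in pre.axons:
            for post in neurons:
                if post.id == pre.id or post.dendrite is None:
                    continue
                meetings = find_meetings(axon, post, fp, crossing)
                for m_idx, loc in enumerate(meetings):
                    if rng.uniform() < p:
                        synapses.append(Synapse(pre.id, post.id, loc, m_idx))
    return Connectome(neurons=list(neurons), synapses=synapses)


# ---------------------------------------------------------------------------
# export


def export_connectome(
    c: Connectome, out_dir: str | Path, basename: str = "connectome"
) -> dict[str, Path]:
    """Write the directed edge list as CSV and the graph as GraphML.

    The CSV has one row per synapse (pre, post, x, y, side, meeting_index);
    the GraphML file is a directed multigraph with one edge per synapse, so
    edge counts in the two files always agree.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{basename}_edges.csv"
    gml_path = out_dir / f"{basename}.graphml"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pre", "post", "x", "y", "side", "meeting_index"])
        for s in c.synapses:
            side = 1 if s.location[1] >= 0 else -1
            w.writerow(
                [s.pre, s.post, f"{s.location[0]:.6f}", f"{s.location[1]:.6f}",
                 side, s.meeting_index]
            )
    g = nx.MultiDiGraph()
    for n in c.neurons:
        g.add_node(n.id, type=n.type_name, x=n.soma[0], y=n.soma[1])
    for s in c.synapses:
        g.add_edge(s.pre, s.post, x=s.location[0], y=s.location[1],
                   meeting_index=s.meeting_index)
    nx.write_graphml(g, gml_path)
    return {"edges_csv": csv_path, "graphml": gml_path}


def read_edge_list(csv_path: str | Path) -> list[Synapse]:
    """Read back an exported edge-list CSV (round-trips export_connectome)."""
    out = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Synapse(
                    pre=row["pre"],
                    post=row["post"],
                    location=(float(row["x"]), float(row["y"])),
                    meeting_index=int(row["meeting_index"]),
                )
            )
    return out
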