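"""File formats: SWC morphology export and the flat trajectory CSV dialect.

SWC files carry one neuron each: a soma point (type 1) followed by the
primary axon chain (type 2) and any secondary axon chain parented at its
branch node.  Points are 2-D with z = 0 and a placeholder radius of 0.5 µm.

The trajectory CSV dialect is one row per point:
``neuron_id, axon_flag, point_index, x, y, stage``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .growth import AxonTrajectory

__all__ = [
    "write_swc",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

SWC_SOMA = 1
SWC_AXON = 2
SWC_RADIUS = 0.5


def write_swc(
    path: str | Path,
    soma: tuple[float, float],
    axons: Sequence[AxonTrajectory],
) -> Path:
    """Write one neuron's morphology as SWC.

    The soma is node 1; each primary axon chains from it.  A secondary axon
    chains from the primary node nearest its branch point (or from the soma
    if no primary precedes it).
    """
    path = Path(path)
    lines = [f"1 {SWC_SOMA} {soma[0]:.3f} {soma[1]:.3f} 0.0 {SWC_RADIUS} -1"]
    next_id = 2
    primary_node_of_index: dict[int, int] = {}
    for axon in axons:
        if axon.kind == "primary":
            parent = 1
            for i, (x, y) in enumerate(axon.points):
                lines.append(
                    f"{next_id} {SWC_AXON} {x:.3f} {y:.3f} 0.0 {SWC_RADIUS} {parent}"
                )
                primary_node_of_index[i] = next_id
                parent = next_id
                next_id += 1
    for axon in axons:
        if axon.kind == "secondary":
            parent = primary_node_of_index.get(
                axon.branch_point if axon.branch_point is not None else -1, 1
            )
            # the branch point coincides with a primary node; skip point 0
            for x, y in axon.points[1:]:
                lines.append(
                    f"{next_id} {SWC_AXON} {x:.3f} {y:.3f} 0.0 {SWC_RADIUS} {parent}"
                )
                parent = next_id
                next_id += 1
    path.write_text("\n".join(lines) + "\n")
    return path


def write_trajectory_csv(
    path: str | Path, trajectories: Iterable[AxonTrajectory]
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["neuron_id", "axon_flag", "point_index", "x", "y", "stage"])
        for t in trajectories:
            for i, ((x, y), stage) in enumerate(zip(t.points, t.stages)):
                w.writerow([t.neuron_id, t.kind, i, f"{x:.6f}", f"{y:.6f}", stage])
    return path


def read_trajectory_csv(path: str | Path) -> list[AxonTrajectory]:
    """Read the flat trajectory dialect back into AxonTrajectory objects."""
    groups: dict[tuple[str, str], list[tuple[int, float, float, str]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["neuron_id"], row["axon_flag"])
            groups.setdefault(key, []).append(
                (int(row["point_index"]), float(row["x"]), float(row["y"]), row["stage"])
            )
    out = []
    for (nid, kind), rows in groups.items():
        rows.sort()
        pts = np.array([[x, y] for _, x, y, _ in rows])
        stages = [s for _, _, _, s in rows]
        out.append(
            AxonTrajectory(pts, stages, neuron_id=nid, kind=kind)  # type: ignore[arg-type]
        )
    return out
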