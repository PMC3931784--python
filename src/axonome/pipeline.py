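"""End-to-end runs: grow populations, fit parameters, assemble connectomes.

Each run function takes a validated :class:`~axonome.config.RunConfig`,
derives named RNG substreams from the master seed, and writes its artifacts
plus a provenance record (config hash, seed, package version) sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import (
    RunConfig,
    build_type_spec,
    config_hash,
    load_anatomy,
    spawn_rng,
)
from .connectome import (
    Connectome,
    Neuron,
    assign_dendrite,
    assign_soma_dv_and_angle,
    export_connectome,
    form_synapses,
    place_somata,
)
from .fitting import (
    CostEvaluator,
    PatternSearchOptions,
    compare_sets,
    pattern_search,
)
from .generalize import fit_ecdf, sample_1d
from .growth import (
    AxonTrajectory,
    NeuronTypeSpec,
    grow_primary,
    grow_secondary,
)
from .io import read_trajectory_csv, write_swc, write_trajectory_csv

__all__ = ["grow_neuron", "run_grow", "run_fit", "run_connectome"]

log = logging.getLogger(__name__)


def _provenance(cfg: RunConfig, extra: dict | None = None) -> dict:
    rec = {"config_hash": config_hash(cfg.data), "seed": cfg.seed,
           "version": __version__}
    if extra:
        rec.update(extra)
    return rec


def grow_neuron(
    spec: NeuronTypeSpec,
    soma: tuple[float, float],
    angle_deg: float,
    field,
    rng: np.random.Generator,
    neuron_id: str = "",
) -> list[AxonTrajectory]:
    """Grow one neuron's primary (and, if configured, secondary) axon.

    Lengths, branch position and branch angle are drawn from the type's
    anatomy samples by 1-D generalization.  A secondary axon is skipped when
    the primary's eligible branching region is too short (truncated growth).
    """
    if spec.samples is None:
        raise ValueError(f"type {spec.name!r} has no anatomy samples")
    length_cdf = fit_ecdf(spec.samples.lengths)
    length = sample_1d(length_cdf, float(rng.uniform()))
    primary = grow_primary(spec, soma, angle_deg, length, field, rng,
                           neuron_id=neuron_id)
    axons = [primary]
    if spec.has_secondary and spec.samples.branch_distance is not None:
        ref = primary.crossed_at if spec.crossing else primary.main_start
        if ref is not None and ref < len(primary) - 1:
            bd_cdf = fit_ecdf(spec.samples.branch_distance)
            ba_cdf = fit_ecdf(spec.samples.branch_angle)
            branch_d = sample_1d(bd_cdf, float(rng.uniform()))
            branch_d = min(branch_d, (len(primary) - 1 - ref) * 1.0)
            branch_a = sample_1d(ba_cdf, float(rng.uniform()))
            sec_length = sample_1d(length_cdf, float(rng.uniform()))
            axons.append(
                grow_secondary(primary, spec, branch_d, branch_a, sec_length,
                               field, rng)
            )
    return axons


def run_grow(cfg: RunConfig, type_name: str, n: int, samples_dir: str | Path,
             out_dir: str | Path) -> dict:
    """Grow ``n`` neurons of one type and write SWC + trajectory CSV."""
    field = cfg.field()
    if type_name not in cfg.data["types"]:
        from .config import ConfigError

        raise ConfigError(
            f"unknown type {type_name!r} (known: {sorted(cfg.data['types'])})"
        )
    spec = build_type_spec(cfg.data, type_name,
                           samples=load_anatomy(samples_dir, type_name))
    pop = cfg.data["population"].get(type_name, {})
    rc_range = tuple(pop.get("rc_range", list(field.rc_extent)))
    side = int(pop.get("side", 1))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    place_rng = spawn_rng(cfg.seed, "placement", type_name)
    somata = place_somata([(type_name, n, rc_range)], field, place_rng,
                          min_sep=float(cfg.data["synapses"]["min_separation"]))
    all_axons: list[AxonTrajectory] = []
    for i, (_, x) in enumerate(somata):
        nid = f"{type_name}-{i}"
        rng = spawn_rng(cfg.seed, "growth", nid)
        dv, angle = assign_soma_dv_and_angle(spec.samples.start_dv_angle, rng)
        soma = (x, side * dv)
        axons = grow_neuron(spec, soma, angle, field, rng, neuron_id=nid)
        all_axons.extend(axons)
        write_swc(out_dir / f"{nid}.swc", soma, axons)
    write_trajectory_csv(out_dir / "trajectories.csv", all_axons)
    prov = _provenance(cfg, {"type": type_name, "n": n})
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    log.info("grew %d %s neurons (%d axons)", n, type_name, len(all_axons))
    return {"neurons": n, "axons": len(all_axons), "out_dir": str(out_dir)}


def run_fit(cfg: RunConfig, type_name: str, real_axons_csv: str | Path,
            samples_dir: str | Path, out_dir: str | Path,
            max_evaluations: int | None = None) -> dict:
    """Fit the four main-stage parameters to a set of real axon trajectories."""
    field = cfg.field()
    anatomy = load_anatomy(samples_dir, type_name)
    spec = build_type_spec(cfg.data, type_name, samples=anatomy)
    real = [t.points for t in read_trajectory_csv(real_axons_csv)]
    if not real:
        raise ValueError(f"no trajectories in {real_axons_csv}")
    fit = cfg.data["fitting"]
    evaluator = CostEvaluator(
        real_axons=real,
        length_cdf=fit_ecdf(anatomy.lengths),
        start_sample=anatomy.start_dv_angle,
        field=field,
        rc_sign=spec.schedule.main.rc_sign,
        n_model_axons=int(fit["n_model_axons"]),
        kappa=float(fit["kappa"]),
        bin_width=float(fit["bin_width"]),
        seed=cfg.seed,
    )
    options = PatternSearchOptions(
        initial_mesh=float(fit["initial_mesh"]),
        expansion=float(fit["expansion"]),
        contraction=float(fit["contraction"]),
        mesh_tolerance=float(fit["mesh_tolerance"]),
        max_evaluations=int(max_evaluations or fit["max_evaluations"]),
    )
    m = spec.schedule.main
    x0 = np.array([m.gamma_rostral, m.gamma_dorsal, m.gamma_ventral, m.alpha])
    result = pattern_search(evaluator, x0, options,
                            rng=spawn_rng(cfg.seed, "pattern-search"))
    best = dataclasses.replace(
        m, gamma_rostral=float(result.x[0]), gamma_dorsal=float(result.x[1]),
        gamma_ventral=float(result.x[2]), alpha=abs(float(result.x[3])))
    model = evaluator.grow_model_set(best, spawn_rng(cfg.seed, "fit-report"))
    report = compare_sets(real, [t.points for t in model],
                          bin_width=float(fit["bin_width"]),
                          dv_halfwidth=field.dv_halfwidth)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_lines = [
        f"{ev}\t{x[0]:.4f}\t{x[1]:.4f}\t{x[2]:.4f}\t{x[3]:.4f}\t{f:.6f}\t{mesh:.5f}"
        for ev, x, f, mesh in result.trace
    ]
    (out_dir / "fit_trace.tsv").write_text(
        "eval\tg_rostral\tg_dorsal\tg_ventral\talpha\tF\tmesh\n"
        + "\n".join(trace_lines) + "\n"
    )
    record = {
        "best": {"gamma_rostral": float(result.x[0]),
                 "gamma_dorsal": float(result.x[1]),
                 "gamma_ventral": float(result.x[2]),
                 "alpha": abs(float(result.x[3]))},
        "F": result.F,
        "evaluations": result.evaluations,
        "progressed": result.progressed,
        "tortuosity_t": report.t_statistic,
        "tortuosity_p": report.t_pvalue,
        "histogram_chi2": report.chi2_statistic,
        "histogram_p": report.chi2_pvalue,
        "provenance": _provenance(cfg, {"type": type_name}),
    }
    (out_dir / "fit_result.json").write_text(json.dumps(record, indent=2))
    return record


def build_connectome(cfg: RunConfig, samples_dir: str | Path) -> Connectome:
    """Run the full placement → dendrites → growth → synapses pipeline."""
    field = cfg.field()
    min_sep = float(cfg.data["synapses"]["min_separation"])
    specs: dict[str, NeuronTypeSpec] = {}
    pop_specs = []
    sides: dict[str, int] = {}
    for tname, p in cfg.data["population"].items():
        if p["count"] <= 0:
            continue
        specs[tname] = build_type_spec(cfg.data, tname,
                                       samples=load_anatomy(samples_dir, tname))
        pop_specs.append((tname, int(p["count"]), tuple(p["rc_range"])))
        sides[tname] = int(p.get("side", 1))
    placed = place_somata(pop_specs, field, spawn_rng(cfg.seed, "placement"),
                          min_sep=min_sep)
    neurons: list[Neuron] = []
    counters: dict[str, int] = {}
    for tname, x in placed:
        spec = specs[tname]
        i = counters.get(tname, 0)
        counters[tname] = i + 1
        nid = f"{tname}-{i}"
        rng = spawn_rng(cfg.seed, "growth", nid)
        dv, angle = assign_soma_dv_and_angle(spec.samples.start_dv_angle, rng)
        soma = (x, sides[tname] * dv)
        axons = grow_neuron(spec, soma, angle, field, rng, neuron_id=nid)
        dendrite = None
        if spec.samples.dendrite_extent is not None:
            dendrite = assign_dendrite(spec.samples.dendrite_extent, rng,
                                       field.dv_halfwidth)
        neurons.append(Neuron(id=nid, type_name=tname, soma=soma,
                              dendrite=dendrite, axons=axons,
                              synapse_class=spec.synapse_class))
    c = form_synapses(
        neurons,
        spawn_rng(cfg.seed, "synapses"),
        p_default=float(cfg.data["synapses"]["p_default"]),
        p_sensory=float(cfg.data["synapses"]["p_sensory"]),
        field=field,
        type_specs=specs,
    )
    c.provenance = _provenance(cfg)
    return c


def run_connectome(cfg: RunConfig, samples_dir: str | Path,
                   out_dir: str | Path, write_swc_files: bool = True) -> dict:
    """Assemble a connectome and write all artifacts plus a summary log."""
    c = build_connectome(cfg, samples_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = export_connectome(c, out_dir)
    all_axons = [a for n in c.neurons for a in n.axons]
    write_trajectory_csv(out_dir / "trajectories.csv", all_axons)
    if write_swc_files:
        swc_dir = out_dir / "swc"
        swc_dir.mkdir(exist_ok=True)
        for n in c.neurons:
            write_swc(swc_dir / f"{n.id}.swc", n.soma, n.axons)
    per_type: dict[str, int] = {}
    for n in c.neurons:
        per_type[n.type_name] = per_type.get(n.type_name, 0) + 1
    summary = {
        "neurons_per_type": per_type,
        "axons": len(all_axons),
        "synapses": len(c.synapses),
        "provenance": c.provenance,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("connectome: %d neurons, %d synapses", len(c.neurons),
             len(c.synapses))
    return summary
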