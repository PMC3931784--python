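# axonome

Developmental generation of neuronal connectivity for the hatchling
*Xenopus* tadpole spinal cord: instead of prescribing which neurons
connect, **axonome** grows every axon under gradient guidance in a 2-D
"opened-book" model of the hindbrain and rostral spinal cord, places
dendrites from small measured samples, and lets synapses form
probabilistically wherever an axon meets a dendrite.  It is written for
computational neuroanatomists who need biologically plausible whole-cord
connectomes from limited anatomical data, and for modellers who want a
tested, seed-reproducible implementation of gradient-based axon growth.

## The model

An axon tip at (x, y) with heading θ advances in fixed Δ = 1 µm steps:

    θ_{k+1} = θ_k ± g_R (G_R·n) + g_D (G_D·n) + g_V (G_V·n) + ξ_k
    x_{k+1} = x_k + Δ cos θ_{k+1},   y_{k+1} = y_k + Δ sin θ_{k+1}

where `G_D` and `G_V` are exponential guidance gradients from the dorsal
edge and the ventral floor plate (concentration `10^(−d/d₁₀)`, with `d₁₀`
the distance over which the cue decays to 10%), `G_R` is a constant
rostral polarity cue, `n` is the unit normal to the heading, `g_R, g_D,
g_V` are signed per-neuron-type sensitivities (attraction > 0), the ±
selects ascending/descending growth, and `ξ_k ~ U[−α, α]` is angular
noise.  Primary axons pass through outgrowth → orientation → main stages
(commissural types cross the floor plate during outgrowth; sensitivities
relax exponentially during orientation); secondary axons branch off and
run the opposite way.  Around this core the package provides:

* **generalization** from small samples — piecewise-linear inverse-ECDF
  sampling for 1-D quantities (lengths, branch geometry) and a smoothed
  bootstrap for correlated pairs (start position + outgrowth angle,
  dendrite extents);
* **fitting** of the four main-stage parameters (g_R, g_D, g_V, α) by
  generalized pattern search on the noisy cost
  `F = Q + κ (T_real − T_model)²` (dorso-ventral histogram chi-square
  distance plus squared mean-tortuosity difference);
* **connectome assembly** — soma placement at ≥ 1.5 µm longitudinal
  separation, dendrite bars, axon growth, and Bernoulli synapse formation
  at each axon–dendrite meeting (probability 0.46; 0.63 for
  sensory-pathway connections);
* **synthetic fixtures** replacing the unpublished measured datasets, so
  the full pipeline runs self-contained.

See `docs/methods.md` for assumptions, calibration constants and
limitations.

## Worked example

```sh
axonome fixtures --out demo/samples --seed 1
axonome connectome --samples demo/samples --out demo/conn --seed 1 --no-swc
```

prints

```
wrote 10 anatomy sample files to demo/samples
INFO axonome.pipeline: connectome: 260 neurons, 2152 synapses
neurons: {'aIN-like': 68, 'cIN-like': 192}  synapses: 2152
```

The first command writes synthetic anatomy samples (axon lengths, start
position/angle clouds, branch geometry, dendrite extents) for the two
demo neuron types.  The second places 68 uncrossed ascending
interneuron-like and 192 commissural interneuron-like somata on one side
of a 2,000 µm cord, grows 519 axons (primary + secondary; a handful of
commissural axons legitimately fail to cross and carry no branch), and
forms 2,152 synapses at axon–dendrite meetings.  `demo/conn/` then holds
the directed edge list (`connectome_edges.csv`), a GraphML graph, the
trajectory CSV, and `summary.json` with counts and a provenance record
(config hash + seed) sufficient to reproduce the run bit-identically.

The same library surface is importable directly — e.g.
`axonome.grow_primary`, `axonome.fixed_point` (the dorso-ventral height
longitudinal growth converges to), `axonome.pattern_search` — and
`axonome fit` fits main-stage parameters to a trajectory CSV of measured
axons.

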