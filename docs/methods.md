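# Methods

## The growth model

An axon is grown as a discrete trajectory of tip positions in a 2-D
"opened-book" representation of the hatchling *Xenopus* tadpole hindbrain
and rostral spinal cord: the roughly cylindrical cord is cut along the
dorsal midline — which no axon crosses — and flattened, so the two sides
become rectangles joined at the ventral floor plate.  Coordinates are in
µm: `x` rostro-caudal (0 at the midbrain–hindbrain border, increasing
caudally, 2,000 µm modelled by default) and `y` signed dorso-ventral with
the ventral midline at 0, the floor plate at |y| < 25 and the dorsal edge
at |y| = 145.  The side of the cord is the sign of `y`, which makes a
floor-plate crossing a continuous trajectory through `y = 0`.

At each step the tip advances exactly Δ = 1 µm and its heading θ (radians,
0 = caudal, π = rostral) is updated by the projections of three guidance
cues onto the unit normal of the current heading, n = θ rotated +90°:

    θ' = θ + s·g_R (G_R·n) + g_D (G_D·n) + g_V (G_V·n) + ξ
    x' = x + Δ cos θ',   y' = y + Δ sin θ'

* `G_D`, `G_V` are exponential gradients from the dorsal edge (source at
  |y| = 145) and from lines flanking the floor-plate midline (|y| = 5).  A
  cue's concentration at distance d from its source is `10^(−d/d₁₀)` where
  `d₁₀` is the distance over which it decays to 10% (default 50 µm for
  both; the model is insensitive to the exact value provided the gradients
  are relatively fast-decaying and the sensitivities are calibrated to
  match).  The projected term uses the analytic spatial gradient, magnitude
  `value · ln10 / d₁₀`, pointing at the source; the ventral cue is flat
  (zero gradient) inside its |y| ≤ 5 plateau.
* `G_R` is a rostral **polarity** cue: slope zero, so it contributes its
  fixed unit direction (−x) scaled by the constant value 1.  The sign
  `s = ±1` selects ascending (+1) or descending (−1) growth.
* `g_R, g_D, g_V` are signed per-type sensitivities (positive = attraction)
  and `ξ ~ Uniform[−α, +α]` is fresh angular noise each step.

An important scale asymmetry follows from this construction: the polarity
term projects with magnitude O(1) while gradient terms project with
magnitude O(ln10/d₁₀) ≈ 0.046 at the source and far less away from it.
"Weak" rostral sensitivities must therefore be numerically tiny (~0.005)
to be comparable to gradient influences, while `g_R` of order 0.1–1 acts
as a strong heading damper.  The angular update is a damped map in θ;
its gain (`g_R` near longitudinal headings) must stay below 2 for stable
alignment, which bounds usable orientation-stage rostral sensitivities.

### Barriers

Five longitudinal barrier rows per side deflect axons: 25 µm (outer margin
of the floor plate, whole field, inactive during the outgrowth stage so
commissural axons can enter the floor plate), 125 and 127 µm (dli
sensory-pathway soma column, caudal of x = 700 µm), 137 µm (Rohon-Beard
soma column, caudal of x = 500 µm) and 145 µm (dorsal growth limit for
the rostral part, x < 500 µm, where those columns are absent); the dorsal
rows block only dorsal-going growth.  On contact the axon is turned
longitudinally.  Two equivalent formulations exist in the code: the
standalone `apply_barriers` clamps the offending step on its own segment
at the barrier line (useful for contact analysis), while the growth loops
redirect the whole Δ step longitudinally from the previous point, which
preserves the exact 1 µm spacing of trajectory points.  The dorso-ventral
field edge (the cut dorsal midline) is treated as an always-active barrier.
A soma placed exactly on a barrier line is nudged 0.5 µm off it.

### Stages

Primary axons run three irreversible stages.  *Outgrowth*: fixed
sensitivities; for uncrossed types it ends once the longitudinal offset
from the origin reaches a small threshold (default 5 µm), for commissural
types when the tip emerges from the floor plate on the side opposite the
origin (|y| > 25 with opposite sign; the ~90° crossing angle emerges from
the outgrowth parameters rather than being enforced).  *Orientation*:
sensitivities relax exponentially from a start vector to the main vector,
`g_i(L) = g_i,main + (g_i,start − g_i,main)·exp(−λ_i L)` with `L` the path
length since orientation onset; α is not scheduled.  *Main*: fixed
main-stage sensitivities.  The orientation→main label switch happens at
the first point whose longitudinal offset reaches 100 µm, measured from
the origin for uncrossed axons and from the floor-plate exit point for
crossed ones (for crossed axons the sensitivity transition is likewise
measured from the exit, and the configured schedule encodes the
post-crossing sign reversal of the ventral response: attraction before the
floor plate, repulsion after).  Secondary axons start at a branch point on
the primary — arc-length distance measured from the start of the eligible
region, i.e. the first main-stage point (uncrossed) or the floor-plate
exit (crossed) — with a sampled branch angle, and run a single main stage
in the longitudinal direction opposite to the primary.

### The dorso-ventral fixed point

For constant sensitivities and longitudinal heading the dorsal and ventral
torques balance at a height y\* found by bisection on
`−g_D·m_D(y) + g_V·m_V(y)` over the marginal zone (25, 145).  The balance
is *stable* only when both cues are repulsive (negative sensitivities):
since each gradient strengthens toward its source, mutual attraction is a
runaway and growth pins at the nearer edge.  The shipped main-stage
defaults therefore use dorsal and ventral repulsion, consistent with
post-crossing ventral repulsion and roof-plate repellents.  Zero-noise
growth converges to y\* (the convergence length scale is set by the
sensitivity magnitudes; with the defaults the e-folding distance is of
order 1 mm, so realistic-length axons approach but need not reach y\*);
realistic noise (α ≈ 0.2) masks the attractor and spreads terminals widely.

## Generalization from small samples

* 1-D: the sample's empirical CDF is approximated piecewise-linearly with
  knots at plotting positions (i−1)/(k−1) over the sorted values (ties
  collapsed), and inverted at a uniform w ∈ [0, 1].  w = 0/1 give the
  sample extremes; every generated value lies inside the observed range.
* 2-D (correlated pairs such as dorso-ventral start position and outgrowth
  angle, or dendrite extremes): a smoothed bootstrap — draw a measured
  pair uniformly, jitter each component with an independent Gaussian
  kernel, reject-and-redraw outside the valid rectangle (cap 1,000).
  Default bandwidths follow the per-dimension Silverman rule; both are
  config-exposed.

## Fitting the four main-stage parameters

Model axons for fitting are grown as single-stage longitudinal
trajectories from generalized start heights and lengths.  The cost is
`F = Q + κ (T_real − T_model)²` where `Q = Σ (p_i − q_i)²/(p_i + q_i)` is
the chi-square distance between pooled dorso-ventral histograms (|y| of
all points at 1 µm arc spacing, 10 µm bins tiling [0, 145]; measured
polylines are densified to 1 µm first) and `T` is mean tortuosity
(arc/chord after 10 µm arc-length resampling, loops excluded and logged).
κ defaults to 300, chosen so the two terms are of the same order: Q
differences are O(0.03–0.1) while squared tortuosity differences for
realistic mismatches are O(10⁻⁴–10⁻³).

Because each evaluation re-grows a finite stochastic axon set, F is a
noisy objective (right-skewed across repeated evaluations at fixed
parameters, with the bulk of the mass at low cost).  It is minimised by a
generalized pattern search: poll the 2×4 coordinate directions (random
order) scaled by the mesh and a per-parameter scale, accept the first
improvement and expand the mesh (×2), contract (×0.5) on a full failed
poll, stop at mesh tolerance 10⁻³ or the evaluation budget.  The
incumbent's cost is re-evaluated each round — without this, one lucky
draw becomes an unbeatable incumbent (winner's curse) and the search
stalls.  Every evaluation consumes a substream derived from (run seed,
evaluation counter) so whole optimizations are reproducible.

Recovery quality is assessed as in the source analyses: a model set grown
at the optimum is compared with the reference set by a Welch t-test on
per-axon tortuosities and a two-sample chi-square on the dorso-ventral
histograms.  The chi-square uses an effective sample size of one
observation per axon because successive 1 µm points on an axon are
strongly autocorrelated; with raw point counts the test would be wildly
anti-conservative.  The caveat travels with every report.

## Connectome assembly

Somata are placed consecutively by type along the rostro-caudal axis,
each drawn from its type's range (uniform by default) and redrawn until
≥ 1.5 µm from every previously placed soma.  Each neuron receives a
(dorso-ventral position, outgrowth angle) pair and a dendrite bar
(d_low, d_high at the soma's x, zero rostro-caudal width, swap-and-clip
if noise inverts the draw) by 2-D generalization, then grows its primary
and, where configured, secondary axon.  A meeting is an axon segment
whose x-interval brackets a dendrite's x (half-open, so one traversal
counts once), whose interpolated y lies within the bar, on the bar's side;
the outgrowth-stage portion of commissural axons inside the floor plate
forms no meetings.  Each meeting independently becomes a synapse with
probability 0.46 (most connections) or 0.63 (sensory-pathway presynaptic
types); multiple synapses per cell pair are allowed, one per distinct
meeting.  Everything downstream of one master seed uses named substreams
(placement, per-neuron growth, synapses, per-evaluation fitting), so a
connectome is bit-reproducible from (config, seed).

## Synthetic anatomy

The measured tadpole datasets behind the original analyses are not
publicly deposited.  The fixtures module generates structurally matched
synthetic samples: truncated log-normal axon lengths inside published
ranges (the cIN-like sample reproduces the published size and range,
k = 46 in 110–1450 µm), correlated Gaussian (dv, angle) start clouds with
ventrally directed angles, uniform branch distances, Gaussian branch
angles and dendrite extents clipped to the marginal zone.  Passing tests
against these fixtures therefore demonstrates the machinery (growth,
generalization, fitting, assembly) under realistic shapes and printed
ranges — not agreement with the real tadpole anatomy, whose distributional
details the fixtures do not imitate.  Figure-level results that depend on
the measured data (e.g. the exact per-type optimized parameter values or
the 17,725-synapse example realization) are correspondingly out of reach;
the demo two-type connectome (68 + 192 neurons on one side) produces a
few thousand synapses, the exact count depending on fixture anatomy.

## Numerical and design choices

* Angles are stored in radians wrapped to (−π, π]; interfaces use degrees.
* Default per-stage sensitivities are calibration constants chosen for the
  qualitative behaviours the model must show: stable interior fixed point
  (main-stage repulsion −4/−4), reliable ballistic floor-plate crossing
  (outgrowth g_V = 1.5, g_R = 0.005, α = 0.02 for the commissural type),
  realistic wiggliness (main g_R = 0.05, α = 0.2 giving tortuosity
  ≈ 1.06 ± 0.02 and dorso-ventral wander of ±10–20 µm).
* Truncation: an axon reaching the rostro-caudal boundary stops and is
  flagged; its trajectory keeps all contract properties.
* Degenerate inputs: all-identical 1-D samples give a degenerate CDF
  (every w maps to the value); duplicate polyline points are dropped with
  a warning; closed loops are excluded from tortuosity means with a log
  entry; infeasible soma packing and exhausted rejection sampling raise
  informative errors.
* Problem sizes in the test-suite experiments (reference sets of 40 axons,
  50 axons per cost evaluation, ≤ 500 evaluations, 100-seed placement
  sweeps) are the package's chosen desk-scale operating points; they keep
  each experiment well-powered while completing in seconds to about a
  minute.

## Known limitations

* No axon–axon interactions (fasciculation), no growth-rate modulation
  (fixed 1 µm elongation), no filopodial/molecular mechanics, no 3-D
  growth, no time-varying gradients, and no diffusion PDE for gradient
  formation — cues are static closed-form fields.
* About 1–2% of commissural axons fail to exit the floor plate under the
  default outgrowth noise and wander inside it; they never reach the
  orientation stage (real crossing is near-certain, aided by mechanisms
  outside this model's scope).
* The two-sample chi-square on histograms is indicative only (points are
  autocorrelated; effective-n correction is a pragmatic, documented fix).
* Synaptic strengths, signs, pruning and the downstream functional network
  are out of scope.
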