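# Methods

`sporesim` is a desk-scale re-implementation of SPORE — synaptic plasticity
with online reinforcement learning — embodied in two closed-loop visuomotor
tasks. This note records the model, the numerical choices, what the built-in
benchmark does and does not show, and the design decisions that were genuinely
open.

## The plasticity model

Learning is *synaptic sampling*: instead of converging to a point estimate,
the vector of synaptic parameters θ follows a Langevin stochastic differential
equation whose stationary distribution is proportional to `p(θ) · V(θ)` — a
prior times the expected discounted reward. High-reward network
configurations are visited often; a temperature parameter `T` flattens
(explores) or sharpens (exploits) that distribution.

Each plastic synapse integrates five local variables:

* `y` — the pre-synaptic spike train filtered with a PSP kernel,
* `e` — an eligibility trace, `de/dt = −e/τ_e + w·y·(z_post − ρ_post)`,
  where `z_post` is the post-synaptic spike train (unit-area Dirac pulses) and
  `ρ_post` the post-synaptic neuron's instantaneous rate,
* `g` — a reward-gradient estimate, `dg/dt = −g/τ_g + r(t)·e`, with `r(t)`
  the global, non-negative, exponentially smoothed reward broadcast to every
  synapse,
* `θ` — the sampled parameter,
  `dθ = β(c_p(μ − θ) + c_g·g) dt + √(2Tβ) dW`,
* `w` — the weight, `w = w₀·exp(θ − θ₀)` for `θ > 0` and exactly 0 otherwise
  (retraction; a retracted synapse transmits nothing and, because `e ∝ w`,
  also receives no gradient — it can only re-grow by prior drift or noise).

Under zero reward and no clipping the θ dynamics are an Ornstein–Uhlenbeck
process with stationary law `N(μ, T/c_p)`; a dedicated test recovers this law
empirically, which pins down the drift/diffusion scaling of the
implementation.

**Two-timescale integration.** `y`, `e`, `g` advance by forward Euler every
`dt_fast = 1 ms`; `θ` and `w` advance only every `dt_slow = 100 ms`, and
weights are constant in between. Parameters are clipped to
`[θ_min, θ_max] = [−2, 5]`; the gradient is read through a symmetric clip
`±Δθ_max` (default 1, not stored back). The learning rate anneals as
`β ← β·exp(−λ·600 s)` on a 10-minute grid with `λ = 8.5×10⁻⁵ s⁻¹`, so
`β(t) = β₀·exp(−λ·600·⌊t/600⌋)` exactly (≈40% of `β₀` after 3 h).

**Defaults** (changeable in `SporeConfig`): `T = 0.1`, `β₀ = 10⁻⁷`,
`μ = 0`, `τ_g = 50 s` (the rule's "integration time"), `τ_e = 2 s`,
`τ_psp = 20 ms`, `c_g = 1`, `w₀ = 1`, `θ₀ = 0`. Initial parameters are
drawn from `N(0.8, 0.6²)` clipped at 0 from below. Several of these
(`τ_e`, `c_g`, `Δθ_max`, `w₀`, `θ₀`) are not published constants; the values
here are plain defaults, exposed in config, and the weak-weight metric
operates on `w` (threshold 0.07) rather than θ so it stays meaningful under
any projection constants.

## Neurons and networks

The neural simulator behind the original experiments is replaced by the
simplest neuron for which `ρ_post` is well defined: an exponential-intensity
point process. `u = Σ w·y` over afferents, `ρ = ρ₀·exp(u/Δu)` capped at
`ρ_max` (defaults 10 Hz, 1, 500 Hz), spikes drawn per fast step with
probability `p = 1 − exp(−ρ·dt)`. No refractory period. Update order within
a fast step is fixed (inputs → traces → exploration chain → potentials →
rates → spikes → plasticity → decode → environment → reward), making rasters
bit-reproducible from one seed.

*Reaching*: 16×16 visual neurons (one per pixel) plus 2×16 row/column axis
feature neurons, all-to-all to 8 motor neurons with multiplicity 10 — 23,040
plastic synapses. A static exploration circuit (35 Hz noise source → weight
750 → exploration neuron; every visual neuron inhibits it with weights drawn
from `N(−500, 50²)`; it excites all motors with weight 10) sustains motor
drive when the scene is static, since an event camera senses only change.

*Lane following*: the 128×32 sensor is tiled into 16×4 windows of 8×8 px, one
visual neuron each, fully connected to 8 motor neurons with multiplicity 1 —
512 plastic synapses; the first four motors form the "left" steering
population, the last four the "right".

## Vision, decoding, reward

The event camera emits at most one polarized event per pixel per 1 ms frame
when the intensity change since that pixel's last event crosses a threshold
(0.1, linear intensity); the per-pixel reference resets only at emitting
pixels, so slow drifts accumulate until they fire. The reaching encoder
ignores polarity and emits exactly three input spikes per event (pixel, row
axis, column axis). The lane encoder fires each window neuron at
`gain × events-in-window` Hz (default gain 7.8 Hz/event, saturating a full
window near the rate cap).

Motor spikes are low-passed (exact exponential, τ = 100 ms) into activities
`a_k`. Reaching uses the population vector `v = Σ a_k (cos β_k, sin β_k)`
with `β_k = 2πk/N`, times a velocity gain. Lane steering uses the ratio
`(a_L − a_R)/(a_L + a_R)` on a ±100 scale, discretized through boundaries
{−10, −2.5, 2.5, 10} into {∓30°, ∓15°, 0°}; a dominant left population
steers left (negative angle). The printed boundaries exceed the raw ratio's
[−1, 1] range, which forces a scale convention; ×100 (a percent scale) is the
natural reading and is a config field.

Rewards are non-negative by construction (the derivation of the sampling rule
requires it). Reaching: `r = (3/5)·r_v·(r_β + 1)⁵` with `r_β = 1 − β_err/β_lim`
inside the angular tolerance (else 0) and `r_v = |v|` above the speed
threshold (else 0, zeroing the product); `β_lim = 45°`, `v_lim = 0.1 m/s`.
This typeset-ambiguous composite is parsed as coefficient 3/5 and exponent 5,
both config fields. Lane: `r = exp(−0.03·β_err²)·exp(−70·d_err²)` with
`β_err` in **degrees** and `d_err` in meters — only in degrees do the
constants reproduce the designed halving per 5° or 0.1 m (e^−0.75 ≈ e^−0.7 ≈ ½).
The reward stream is smoothed with a first-order filter (τ_r = 0.1 s) before
reaching the synapses. Resets (goal reached; vehicle off-track) teleport the
agent but are never signaled to the learner — no episode boundary exists.

The lane world is a closed rounded-rectangle circuit (10 m × 6 m, corner
radius 2 m, lane half-width 0.4 m), driven at 1 m/s through a kinematic
bicycle model (wheelbase 0.3 m); off-track means lateral error beyond the
half-width. The forward view is a pitched pinhole projection of the two lane
boundaries. Both renderers are procedural; the reaching view draws the ball
disc with a one-pixel soft edge so sub-pixel motion changes intensities
continuously and the event camera responds to slow movement.

## Numerical choices worth knowing

* **Spike-term compensator.** Spikes are Bernoulli draws with
  `p = 1 − exp(−ρ·dt)`. The eligibility update's compensator therefore uses
  the effective per-step intensity `p/dt`, not `ρ` itself: with `ρ·dt` the
  spike term would have mean `(1−e^{−ρdt}) − ρdt < 0` (≈ −0.11 at the rate
  cap), and since rewards are non-negative that bias drives *every* θ
  downward — in pilots it retracted over half of all synapses and made
  learning worse than frozen weights. With the matched compensator the spike
  term is exactly mean-zero at any rate.
* **Euler fidelity.** Integrating the e/g equations at 1 ms agrees with a
  0.01 ms reference to ~0.1% over 10 s when both receive the same input
  signals (spike trains, reward, and the PSP trace as the synapse sees it,
  piecewise-constant on the 1 ms grid). The PSP trace itself, being a 20 ms
  filter stepped at 1 ms, carries an intrinsic O(dt/2τ_psp) ≈ 2.5%
  discretization bias relative to a continuous-time filter; this is a
  property of the production scheme, shared with any 1 ms integrator.
* **Retraction boundary.** With `w₀ = 1, θ₀ = 0` the projection jumps from 0
  to 1 at `θ = 0⁺`, and "weak" (`w < 0.07`) coincides with "retracted"
  (`θ ≤ 0`). Initialization clips ≈9% of parameters to exactly 0, half of
  which immediately un-retract by diffusion; weak-weight counts are best read
  as trends, which is how the tests use them.
* **Determinism.** One seed sequence spawns independent streams (network
  construction, environment resets, per-step spike draws, slow-update noise).
  The reaching loop exists twice: a plain-NumPy reference and a compiled
  (numba) kernel consuming identical pre-drawn variates; an equivalence test
  holds them to the same trajectory, and long runs use the kernel.

## The reduced benchmark

The published learning curves take hours of simulated time at full scale.
The package's built-in benchmark scales the reaching task down so that the
*qualitative* claims — reward-driven improvement over a random policy, and
progressive sparsification — are testable in minutes: 8×8 pixels, 4 motor
neurons, multiplicity 2 (640 plastic synapses), flat prior, `β = 10⁻³`,
30 simulated minutes, five seeds, each paired with a frozen-weight (`β = 0`)
baseline at identical architecture and drive.

Three plumbing constants differ from the full-scale defaults, chosen by
operating-point analysis (not by fitting any published number): `Δu = 2`
keeps the small network's potentials inside the sensitive range of the
exponential rate function instead of pinned at the cap, where weights cannot
modulate behavior; the exploration→motor weight drops to 0.2 for the same
reason; and the velocity gain of 2.5 m/s per unit activity gives the ball a
diffusive transport fast enough to revisit the 2 m target repeatedly within a
window — with slow transport the reach rate vanishes for learner and baseline
alike and the comparison is vacuous. Under these conditions learning runs
climb from ~25 to ~40–90 reaches per 250 s window over half an hour while
frozen baselines stay near 5–30, and the weak-weight count roughly triples.

What passing these tests shows: the full signal path (events → spikes →
eligibility → reward gradient → Langevin updates → behavior) improves the
policy it is supposed to improve, with the right stationary statistics in the
flat-likelihood limit. What it does not show: the published full-scale
numbers (~90 reaches/250 s after hours; 60 s lane retention after 5 h with
annealing), which depend on the original neural simulator's neuron model and
hours of compute; the lane task's learning at scale is likewise out of the
benchmark (its mechanics — encoder, decoder, reward, resets, annealing — are
unit-tested, and the annealing-retention mechanism is tested directly on the
parameter dynamics: an annealed learning rate freezes late-run parameter
dispersion that a constant rate keeps diffusing).

The synthetic worlds idealize real robotics in the usual ways: no sensor
noise or hot pixels, no vehicle or ball inertia, procedural rendering instead
of a physics engine, and a reward computed from ground-truth state. Results
here characterize the learning rule, not a robot.

## Problem sizes used by the test suite

Flat-likelihood sampling: 100 synapses × 10⁶ slow updates. Euler oracle:
10 s at 1 ms vs 0.01 ms. Benchmark: 5 × 2 runs of 1800 s at 1 ms (the
compiled kernel covers one run in under a minute). The acceptance script
repeats the same computations from scratch.
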