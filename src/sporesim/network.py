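"""Stochastic point-process neurons and the two task network topologies.

Neurons are exponential-intensity point processes: the membrane potential ``u``
is a weighted sum of afferent PSP traces, the instantaneous rate is
``rho = rho0 * exp(u / delta_u)`` capped at ``rho_max``, and spikes are drawn
per fast step with probability ``1 - exp(-rho * dt)``.  This gives the
plasticity rule a well-defined instantaneous post-synaptic rate.

Both tasks use a shallow feed-forward architecture: input neurons (driven
directly by encoded camera events) project to motor neurons through plastic
synapses, with an optional multiplicity (several independent plastic synapses
per input/motor pair).  The reaching network adds one static exploration
neuron, excited by a 35 Hz noise source and inhibited by every visual neuron,
that drives the motor layer whenever the scene is static — an event camera
senses only change, so without it a motionless agent would receive no input
and fall silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import LaneConfig, NeuronConfig, ReachingConfig, SporeConfig
from .plasticity import SynapseGroup

__all__ = [
    "NeuronState",
    "NetworkTopology",
    "neuron_rate",
    "sample_spikes",
    "step_network",
    "build_reaching_network",
    "build_lane_network",
]


@dataclass
class NeuronState:
    """Instantaneous state of one point-process neuron."""

    u: float = 0.0
    rho: float = 0.0
    last_spike: float = -math.inf


@dataclass
class NetworkTopology:
    """Populations, plastic synapse array and static wiring for one task.

    ``plastic.w`` has shape ``(n_inputs, n_motor, multiplicity)``; the effective
    input->motor weight is the sum over the multiplicity axis.  Mutable trace
    state (``y_in``, exploration traces, motor rates) lives here so that
    :func:`step_network` is a pure function of (topology, input spikes, rng).
    """

    task: str
    populations: dict[str, int]
    plastic: SynapseGroup
    neuron_cfg: NeuronConfig
    # static exploration wiring (reaching only)
    w_noise_to_exp: float = 0.0
    w_vis_to_exp: np.ndarray | None = None  # per visual neuron, negative
    w_exp_to_motor: float = 0.0
    noise_rate: float = 0.0
    n_visual: int = 0  # visual inputs precede axis inputs in the input ordering
    tau_psp: float = 0.02
    dt_fast: float = 0.001
    # mutable trace state
    y_in: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    y_noise: float = 0.0
    y_exp: float = 0.0
    motor_rates: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_in, n_motor = self.plastic.w.shape[:2]
        if self.populations.get("motor") != n_motor:
            raise ValueError("motor population size does not match plastic array")
        if sum(self.populations.get(k, 0) for k in ("visual", "axis")) != n_in:
            raise ValueError("input population sizes do not match plastic array")
        if self.w_vis_to_exp is not None and len(self.w_vis_to_exp) != self.n_visual:
            raise ValueError("exploration inhibition must cover every visual neuron")
        self.reset_state()

    @property
    def n_inputs(self) -> int:
        return self.plastic.w.shape[0]

    @property
    def n_motor(self) -> int:
        return self.plastic.w.shape[1]

    @property
    def multiplicity(self) -> int:
        return self.plastic.w.shape[2]

    @property
    def n_plastic(self) -> int:
        return self.plastic.n

    def effective_weights(self) -> np.ndarray:
        """(n_inputs, n_motor) weights, multiplicity summed."""
        return self.plastic.w.sum(axis=2)

    def reset_state(self) -> None:
        self.y_in = np.zeros(self.n_inputs)
        self.y_noise = 0.0
        self.y_exp = 0.0
        self.motor_rates = np.full(self.n_motor, self.neuron_cfg.rho0)


def neuron_rate(u, cfg: NeuronConfig):
    """Instantaneous firing rate of the exponential point-process neuron, Hz."""
    u_cap = cfg.delta_u * math.log(cfg.rho_max / cfg.rho0)
    x = np.minimum(np.asarray(u, dtype=float), u_cap)
    rho = cfg.rho0 * np.exp(x / cfg.delta_u)
    return float(rho) if rho.ndim == 0 else rho


def sample_spikes(rho, dt: float, rng: np.random.Generator):
    """Bernoulli spike draw(s) with per-step probability ``1 - exp(-rho*dt)``."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or dt <= 0:
        raise ValueError("need rho >= 0 and dt > 0")
    p = 1.0 - np.exp(-rho * dt)
    out = rng.random(rho.shape) < p
    return bool(out) if out.ndim == 0 else out


def step_network(top: NetworkTopology, input_counts: np.ndarray, dt: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Advance the network by one fast step.

    Update order within a step: (1) input spike counts update the input PSP
    traces, (2) the exploration chain fires (its trace reaches the motor
    potentials on the same step), (3) motor potentials u = sum w*y, (4) motor
    rates, (5) motor spike sampling.  Returns ``(motor_spikes, motor_rates)``
    for the plasticity update.
    """
    if dt != top.dt_fast:
        raise ValueError("step_network must run at the fast time step")
    decay = 1.0 - dt / top.tau_psp
    top.y_in *= decay
    top.y_in += input_counts

    u_exp_contrib = 0.0
    if top.w_vis_to_exp is not None:
        # exploration chain: noise source -> exploration neuron -> motors
        noise_spike = sample_spikes(top.noise_rate, dt, rng)
        top.y_noise = top.y_noise * decay + float(noise_spike)
        u_exp = top.w_noise_to_exp * top.y_noise + float(
            top.w_vis_to_exp @ top.y_in[: top.n_visual]
        )
        exp_spike = sample_spikes(neuron_rate(u_exp, top.neuron_cfg), dt, rng)
        top.y_exp = top.y_exp * decay + float(exp_spike)
        u_exp_contrib = top.w_exp_to_motor * top.y_exp

    u = top.effective_weights().T @ top.y_in + u_exp_contrib
    rates = neuron_rate(u, top.neuron_cfg)
    spikes = sample_spikes(rates, dt, rng)
    top.motor_rates = rates
    return spikes, rates


def build_reaching_network(cfg: ReachingConfig, spore_cfg: SporeConfig,
                           neuron_cfg: NeuronConfig, rng_seed) -> NetworkTopology:
    """Construct the reaching topology.

    ``pixels x pixels`` visual neurons plus ``2 x pixels`` row/column axis
    feature neurons all project to every motor neuron with ``multiplicity``
    plastic synapses (23,040 learnable parameters at the published 16x16 / 8
    motor / x10 scale), plus the static exploration circuit.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n_visual = cfg.pixels * cfg.pixels
    n_axis = 2 * cfg.pixels
    n_in = n_visual + n_axis
    plastic = SynapseGroup.initialized((n_in, cfg.n_motor, cfg.multiplicity), rng, spore_cfg)
    w_inh = rng.normal(cfg.vis_to_exploration_mean, cfg.vis_to_exploration_sd, size=n_visual)
    return NetworkTopology(
        task="reaching",
        populations={
            "visual": n_visual,
            "axis": n_axis,
            "motor": cfg.n_motor,
            "exploration": 1,
            "noise": 1,
        },
        plastic=plastic,
        neuron_cfg=neuron_cfg,
        w_noise_to_exp=cfg.noise_to_exploration,
        w_vis_to_exp=w_inh,
        w_exp_to_motor=cfg.exploration_to_motor,
        noise_rate=cfg.noise_rate,
        n_visual=n_visual,
        tau_psp=spore_cfg.tau_psp,
        dt_fast=spore_cfg.dt_fast,
    )


def build_lane_network(cfg: LaneConfig, spore_cfg: SporeConfig,
                       neuron_cfg: NeuronConfig, rng_seed) -> NetworkTopology:
    """Construct the lane-following topology.

    One visual neuron per non-overlapping ``window x window`` sensor tile
    (16x4 = 64 at the published 128x32 resolution), fully connected to the
    motor layer; the first half of the motor neurons is the "left" steering
    population, the second half the "right" one.  No exploration neuron: the
    vehicle moves constantly, so the scene always generates events.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    nx = cfg.width // cfg.window
    ny = cfg.height // cfg.window
    n_visual = nx * ny
    plastic = SynapseGroup.initialized((n_visual, cfg.n_motor, cfg.multiplicity), rng, spore_cfg)
    return NetworkTopology(
        task="lane",
        populations={"visual": n_visual, "motor": cfg.n_motor},
        plastic=plastic,
        neuron_cfg=neuron_cfg,
        n_visual=n_visual,
        tau_psp=spore_cfg.tau_psp,
        dt_fast=spore_cfg.dt_fast,
    )
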