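"""Reward-driven synaptic sampling (SPORE) synapse dynamics.

Each plastic synapse carries five dynamic variables:

* ``y`` — the pre-synaptic spike train filtered with a PSP kernel (here a single
  exponential with time constant ``tau_psp``, unit jump per spike),
* ``e`` — an eligibility trace remembering recent pre/post coincidence,
* ``g`` — a slowly averaged estimate of the reward gradient d(expected reward)/d(theta),
* ``theta`` — the synaptic parameter sampled by the Langevin dynamics,
* ``w`` — the non-negative synaptic weight, an exponential projection of ``theta``.

The fast variables (``y``, ``e``, ``g``) advance with the forward-Euler step
``dt_fast`` (1 ms by default); ``theta`` and ``w`` advance only every ``dt_slow``
(100 ms), and weights remain constant between slow updates.  Under a flat
likelihood (zero reward) the parameter dynamics reduce to an Ornstein-Uhlenbeck
process with stationary mean ``mu`` and variance ``temperature / c_p``, which is
the sampling interpretation of the rule: the network does not converge to a
point estimate but keeps drawing parameter vectors from a posterior-like target
distribution (prior times expected reward), sharpened or flattened by the
temperature.

All operations accept scalars or NumPy arrays (broadcasting elementwise), so a
whole synapse population updates in one call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import SporeConfig

__all__ = [
    "SynapseState",
    "AnnealSchedule",
    "update_psp_trace",
    "update_eligibility",
    "update_reward_gradient",
    "update_parameter",
    "parameter_to_weight",
    "anneal_learning_rate",
    "init_parameters",
    "SynapseGroup",
]


@dataclass
class SynapseState:
    """Dynamic variables of one plastic synapse."""

    y: float = 0.0
    e: float = 0.0
    g: float = 0.0
    theta: float = 0.0
    w: float = 0.0


@dataclass
class AnnealSchedule:
    """Piecewise-constant exponential decay of the learning rate.

    ``beta`` is multiplied by ``exp(-lambda_decay * anneal_interval)`` whenever
    simulated time crosses a multiple of ``anneal_interval`` (10 min by
    default), so ``beta(t) = beta0 * exp(-lambda * interval * floor(t/interval))``.
    """

    beta: float
    t_last_update: float = 0.0

    def __post_init__(self) -> None:
        self.beta0 = self.beta


def update_psp_trace(y, pre_spike, cfg: SporeConfig):
    """One fast Euler step of the filtered pre-synaptic trace.

    ``y`` decays with rate ``1/tau_psp``; each pre-synaptic spike adds a unit
    jump.  ``pre_spike`` may be boolean or an integer spike count (an input
    neuron can receive several events within one fast step).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("PSP trace y must be non-negative")
    out = y * (1.0 - cfg.dt_fast / cfg.tau_psp) + np.asarray(pre_spike, dtype=float)
    return float(out) if out.ndim == 0 else out


def update_eligibility(s: SynapseState, post_spike, rho_post, cfg: SporeConfig) -> SynapseState:
    """One fast Euler step of the eligibility trace.

    ``de/dt = -e/tau_e + w * y * (z_post - rho_post)`` where ``z_post`` is a sum
    of Dirac pulses at post-synaptic firing times.  A spike within a fast step
    contributes unit area (indicator, not indicator/dt), making the spike term
    and the rate expectation ``rho_post * dt`` commensurate.
    """
    rho = np.asarray(rho_post, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho_post must be non-negative")
    z = np.asarray(post_spike, dtype=float)
    e = s.e + cfg.dt_fast * (-s.e / cfg.tau_e) + s.w * s.y * (z - rho * cfg.dt_fast)
    e = float(e) if np.ndim(e) == 0 else e
    return replace(s, e=e)


def update_reward_gradient(s: SynapseState, r, cfg: SporeConfig) -> SynapseState:
    """One fast Euler step of the reward-gradient estimate.

    ``dg/dt = -g/tau_g + r * e`` with a non-negative global reward ``r`` — the
    rule's derivation assumes ``r(t) >= 0`` at all times.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("reward must be non-negative")
    g = s.g + cfg.dt_fast * (-s.g / cfg.tau_g + r * s.e)
    g = float(g) if np.ndim(g) == 0 else g
    return replace(s, g=g)


def update_parameter(s: SynapseState, beta: float, noise, cfg: SporeConfig) -> SynapseState:
    """One slow Langevin step of the synaptic parameter, then re-project the weight.

    ``theta += beta * (c_p*(mu - theta) + c_g*g) * dt_slow + sqrt(2*T*beta*dt_slow) * noise``
    with ``g`` clipped symmetrically at ``±dtheta_max`` at read time and ``theta``
    clipped to ``[theta_min, theta_max]`` after the step.  ``noise`` is a standard
    normal draw (the discretized Wiener increment).
    """
    noise = np.asarray(noise, dtype=float)
    if not np.all(np.isfinite(noise)):
        raise ValueError("noise must be finite")
    g_clip = np.clip(s.g, -cfg.dtheta_max, cfg.dtheta_max)
    drift = beta * (cfg.c_p * (cfg.mu - s.theta) + cfg.c_g * g_clip) * cfg.dt_slow
    diff = math.sqrt(2.0 * cfg.temperature * beta * cfg.dt_slow) * noise
    theta = np.clip(s.theta + drift + diff, cfg.theta_min, cfg.theta_max)
    theta = float(theta) if np.ndim(theta) == 0 else theta
    w = parameter_to_weight(theta, cfg)
    return replace(s, theta=theta, w=w)


def parameter_to_weight(theta, cfg: SporeConfig):
    """Exponential projection ``w = w0 * exp(theta - theta0)`` for ``theta > 0``, else 0.

    The hard zero below ``theta = 0`` implements synapse retraction: a synapse
    whose parameter dips below zero is functionally disconnected and can later
    regrow, mimicking spine dynamics.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.where(theta > 0.0, cfg.w0 * np.exp(theta - cfg.theta0), 0.0)
    return float(w) if w.ndim == 0 else w


def anneal_learning_rate(sched: AnnealSchedule, t_now: float, cfg: SporeConfig) -> AnnealSchedule:
    """Advance the annealing schedule to ``t_now``.

    The learning rate is updated only on the ``anneal_interval`` grid: for every
    boundary crossed since the last update, ``beta`` is multiplied by
    ``exp(-lambda_decay * anneal_interval)``.  Between boundaries it is constant,
    so ``beta(t)`` is exactly ``beta0 * exp(-lambda * interval * floor(t/interval))``.
    """
    if t_now < sched.t_last_update:
        raise ValueError("time must not run backwards")
    interval = cfg.anneal_interval
    n_prev = int(sched.t_last_update // interval)
    n_now = int(t_now // interval)
    beta = sched.beta * math.exp(-cfg.lambda_decay * interval * (n_now - n_prev))
    out = AnnealSchedule(beta=beta, t_last_update=t_now)
    out.beta0 = sched.beta0
    return out


def init_parameters(n: int, rng_seed, cfg: SporeConfig) -> list[SynapseState]:
    """Draw ``n`` initial synapse states.

    ``theta`` is drawn from a Gaussian (mean ``init_mean``, s.d. ``init_sd``)
    and clipped at 0 from below; traces start quiescent (``y = e = g = 0``) and
    ``w`` is set by the projection.  ``rng_seed`` may be an int or a Generator.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    theta = np.maximum(rng.normal(cfg.init_mean, cfg.init_sd, size=n), 0.0)
    w = parameter_to_weight(theta, cfg)
    return [SynapseState(theta=float(th), w=float(wi)) for th, wi in zip(theta, w)]


class SynapseGroup:
    """Vectorized population of plastic synapses sharing one config.

    Stores ``e``, ``g``, ``theta``, ``w`` as arrays of a common shape; the
    pre-synaptic trace ``y`` is supplied per fast step by the network (synapses
    sharing a pre-synaptic neuron share its trace).  Used by the closed-loop
    runner; the scalar operations above are the per-synapse reference semantics.
    """

    def __init__(self, theta: np.ndarray, cfg: SporeConfig):
        self.cfg = cfg
        self.theta = np.asarray(theta, dtype=float).copy()
        self.w = parameter_to_weight(self.theta, cfg)
        self.e = np.zeros_like(self.theta)
        self.g = np.zeros_like(self.theta)

    @classmethod
    def initialized(cls, shape, rng, cfg: SporeConfig) -> "SynapseGroup":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        theta = np.maximum(rng.normal(cfg.init_mean, cfg.init_sd, size=shape), 0.0)
        return cls(theta, cfg)

    @property
    def n(self) -> int:
        return self.theta.size

    def fast_step(self, y, post_spike, rho_post, r: float) -> None:
        """Advance e and g by one dt_fast given broadcastable y/post arrays."""
        cfg = self.cfg
        if r < 0:
            raise ValueError("reward must be non-negative")
        dz = np.asarray(post_spike, dtype=float) - np.asarray(rho_post, dtype=float) * cfg.dt_fast
        self.e += cfg.dt_fast * (-self.e / cfg.tau_e) + self.w * y * dz
        self.g += cfg.dt_fast * (-self.g / cfg.tau_g + r * self.e)

    def slow_step(self, beta: float, noise: np.ndarray) -> None:
        """Advance theta by one dt_slow Langevin step and re-project weights."""
        cfg = self.cfg
        g_clip = np.clip(self.g, -cfg.dtheta_max, cfg.dtheta_max)
        drift = beta * (cfg.c_p * (cfg.mu - self.theta) + cfg.c_g * g_clip) * cfg.dt_slow
        self.theta += drift
        self.theta += math.sqrt(2.0 * cfg.temperature * beta * cfg.dt_slow) * noise
        np.clip(self.theta, cfg.theta_min, cfg.theta_max, out=self.theta)
        self.w = parameter_to_weight(self.theta, cfg)
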