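"""Configuration dataclasses for the simulator.

Every tunable constant of the plasticity rule, the neuron model, the event-camera
simulation, the two environments and the motor codecs lives here, with the defaults
used in the published closed-loop experiments.  Configs serialize to/from a single
hierarchical YAML document (blocks ``spore:``, ``network:``, ``vision:``,
``reaching:``, ``lane:``, ``codec:`` under an experiment header).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SporeConfig",
    "NeuronConfig",
    "VisionConfig",
    "ReachingConfig",
    "LaneConfig",
    "CodecConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass
class SporeConfig:
    """Constants of the synaptic-sampling plasticity rule.

    The rule integrates, per synapse, a filtered pre-synaptic trace ``y``, an
    eligibility trace ``e`` (time constant ``tau_e``), a reward-gradient
    estimate ``g`` (time constant ``tau_g``), and a synaptic parameter ``theta``
    that follows a drift-diffusion (Langevin) update with learning rate ``beta``
    and temperature ``temperature``.  Weights are the exponential projection
    ``w = w0 * exp(theta - theta0)`` for ``theta > 0``, zero otherwise.
    """

    tau_psp: float = 0.02  # PSP kernel time constant, s (single exponential)
    tau_e: float = 2.0  # eligibility trace time constant, s (~episode length)
    tau_g: float = 50.0  # reward-gradient averaging time constant, s
    c_p: float = 0.0  # prior strength (0 = flat prior)
    c_g: float = 1.0  # reward-gradient gain
    mu: float = 0.0  # prior mean of synaptic parameters
    temperature: float = 0.1  # diffusion coefficient T of the parameter SDE
    beta0: float = 1e-7  # initial learning rate
    lambda_decay: float = 8.5e-5  # learning-rate annealing rate, 1/s
    theta_min: float = -2.0  # lower clip of synaptic parameters
    theta_max: float = 5.0  # upper clip of synaptic parameters
    dtheta_max: float = 1.0  # symmetric clip on the gradient estimate at read time
    w0: float = 1.0  # weight-projection scale
    theta0: float = 0.0  # weight-projection offset
    init_mean: float = 0.8  # Gaussian mean for initial theta
    init_sd: float = 0.6  # Gaussian s.d. for initial theta (clipped at 0 from below)
    dt_fast: float = 0.001  # fast integration step, s
    dt_slow: float = 0.1  # parameter/weight update interval, s
    anneal_interval: float = 600.0  # seconds between learning-rate updates

    def __post_init__(self) -> None:
        if self.tau_psp <= 0 or self.tau_e <= 0 or self.tau_g <= 0:
            raise ValueError("time constants must be positive")
        if self.c_p < 0 or self.temperature < 0 or self.lambda_decay < 0:
            raise ValueError("c_p, temperature and lambda_decay must be non-negative")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if not self.theta_min < self.theta_max:
            raise ValueError("theta_min must be below theta_max")
        if self.dt_fast <= 0 or self.dt_fast > self.dt_slow:
            raise ValueError("need 0 < dt_fast <= dt_slow")
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")

    @property
    def steps_per_slow(self) -> int:
        return int(round(self.dt_slow / self.dt_fast))


@dataclass
class NeuronConfig:
    """Exponential-intensity point-process neuron.

    Instantaneous rate ``rho = rho0 * exp(u / delta_u)`` capped at ``rho_max``;
    spikes are drawn per fast step with probability ``1 - exp(-rho * dt)``.
    """

    rho0: float = 10.0  # baseline rate at u = 0, Hz
    delta_u: float = 1.0  # potential scale of the exponential nonlinearity
    rho_max: float = 500.0  # rate cap, Hz

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.delta_u <= 0 or self.rho_max < self.rho0:
            raise ValueError("need rho0 > 0, delta_u > 0, rho_max >= rho0")


@dataclass
class VisionConfig:
    """Simulated event camera (DVS) and spike encoders."""

    threshold: float = 0.1  # intensity change per event, linear scale
    lane_gain: float = 7.8125  # Hz per event for the 8x8 windowed lane encoder

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class ReachingConfig:
    """Ball-reaching world: bounded plane, top-down camera, directional reward."""

    plane_half: float = 10.0  # half-extent of the walled plane, m
    ball_radius: float = 2.0  # m
    target_radius: float = 2.0  # m, target disc centred at the origin
    pixels: int = 16  # camera resolution per side (square sensor)
    n_motor: int = 8
    multiplicity: int = 10  # plastic synapses per (input, motor) pair
    beta_lim: float = math.pi / 4  # angular tolerance of the reward, rad
    v_lim: float = 0.1  # speed threshold of the reward, m/s
    reward_coef: float = 0.6  # multiplicative constant of the reward
    reward_exp: float = 5.0  # exponent on (r_beta + 1)
    velocity_gain: float = 1.0  # m/s per unit decoded activity
    noise_rate: float = 35.0  # exploration noise source, Hz
    noise_to_exploration: float = 750.0  # static excitatory weight
    vis_to_exploration_mean: float = -500.0  # static inhibitory weights, Gaussian mean
    vis_to_exploration_sd: float = 50.0
    exploration_to_motor: float = 10.0  # static excitatory weight


@dataclass
class LaneConfig:
    """Lane-following world: closed circuit, forward camera, Gaussian reward."""

    width: int = 128  # sensor width, px
    height: int = 32  # sensor height, px
    window: int = 8  # encoder window side, px
    n_motor: int = 8  # split into two equal steering populations
    multiplicity: int = 1
    speed: float = 1.0  # constant forward speed, m/s
    wheelbase: float = 0.3  # kinematic bicycle wheelbase, m
    lane_halfwidth: float = 0.4  # off-track beyond this lateral error, m
    track_length: float = 10.0  # straight length of the rounded-rectangle circuit, m
    track_width: float = 6.0  # the other straight length, m
    corner_radius: float = 2.0  # m
    # reward: exp(-0.03 beta_err^2) * exp(-70 d_err^2); beta_err in degrees
    angle_coef: float = 0.03  # per degree^2
    dist_coef: float = 70.0  # per m^2
    ratio_scale: float = 100.0  # maps the (-1, 1) decoder ratio onto the boundary scale
    boundaries: tuple[float, ...] = (-10.0, -2.5, 2.5, 10.0)
    angles: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    # camera model for the procedural forward view
    cam_height: float = 0.5  # m above ground
    cam_pitch: float = 0.35  # rad, downward
    focal: float = 40.0  # px
    lookahead: float = 6.0  # m of track rendered ahead


@dataclass
class CodecConfig:
    """Motor decoding and reward conditioning."""

    tau_activity: float = 0.1  # low-pass time constant of motor activities, s
    tau_reward: float = 0.1  # exponential smoothing of the reward stream, s

    def __post_init__(self) -> None:
        if self.tau_activity <= 0 or self.tau_reward <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class ExperimentConfig:
    """Top-level closed-loop experiment description."""

    task: str = "reaching"  # "reaching" | "lane"
    duration: float = 10.0  # simulated seconds
    seed: int = 0
    snapshot_interval: float = 60.0  # seconds between weight snapshots
    annealing: bool = True  # apply learning-rate decay every anneal_interval
    plastic: bool = True  # False freezes the weights (beta = 0 baseline)
    spore: SporeConfig = field(default_factory=SporeConfig)
    network: NeuronConfig = field(default_factory=NeuronConfig)
    vision: VisionConfig = field(default_factory=VisionConfig)
    reaching: ReachingConfig = field(default_factory=ReachingConfig)
    lane: LaneConfig = field(default_factory=LaneConfig)
    codec: CodecConfig = field(default_factory=CodecConfig)

    def __post_init__(self) -> None:
        if self.task not in ("reaching", "lane"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        sub = {
            "spore": SporeConfig,
            "network": NeuronConfig,
            "vision": VisionConfig,
            "reaching": ReachingConfig,
            "lane": LaneConfig,
            "codec": CodecConfig,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        cfg = cls(**d)
        for key in ("boundaries", "angles"):
            setattr(cfg.lane, key, tuple(getattr(cfg.lane, key)))
        return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ExperimentConfig.from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg.to_dict()), fh, sort_keys=False)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable short hash of a config, for run manifests."""
    payload = json.dumps(_jsonable(cfg.to_dict()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
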