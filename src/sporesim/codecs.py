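"""Motor decoding and reward conditioning.

Motor spike trains are low-pass filtered into activities ``a_k`` (exact
exponential decay, unit jump per spike, time constant 100 ms by default).
Two decoders read them out:

* population vector (reaching) — the N motor neurons sit at angles
  ``beta_k = 2*pi*k/N`` on the unit circle and the command is the
  activity-weighted vector sum, so equal activities cancel and rotating the
  activity pattern rotates the command;
* left/right ratio (lane) — the first N/2 activities form the "left"
  population, the rest the "right"; the normalized difference
  ``(a_L - a_R)/(a_L + a_R)``, expressed on a ±100 scale, is discretized into
  five steering angles through fixed decision boundaries.

The scalar reward stream is smoothed by a first-order exponential filter
before being broadcast to every synapse — credit assignment uses one global
scalar, never a per-neuron error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import LaneConfig

__all__ = [
    "MotorActivity",
    "lowpass_activity",
    "decode_velocity",
    "decode_steering",
    "smooth_reward",
]


@dataclass
class MotorActivity:
    """Low-pass-filtered spike activity per motor neuron."""

    a: np.ndarray
    tau: float = 0.1

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if np.any(self.a < 0):
            raise ValueError("activities must be non-negative")


def lowpass_activity(act: MotorActivity, spikes, dt: float) -> MotorActivity:
    """One filter step: exact exponential decay plus a unit jump per spike."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = act.a * math.exp(-dt / act.tau) + np.asarray(spikes, dtype=float)
    return MotorActivity(a=a, tau=act.tau)


def motor_angles(n: int) -> np.ndarray:
    """Preferred direction ``beta_k = 2*pi*k/n`` of motor neuron k = 1..n."""
    return 2.0 * math.pi * np.arange(1, n + 1) / n


def decode_velocity(act: MotorActivity, gain: float = 1.0) -> tuple[float, float]:
    """Population-vector readout: ``v = gain * sum_k a_k * (cos beta_k, sin beta_k)``."""
    ang = motor_angles(len(act.a))
    return (gain * float(np.cos(ang) @ act.a), gain * float(np.sin(ang) @ act.a))


def decode_steering(act: MotorActivity, cfg: LaneConfig | None = None) -> float:
    """Discretized left/right ratio readout, returning a steering angle in degrees.

    The normalized population difference ``(a_L - a_R)/(a_L + a_R)`` lies in
    [-1, 1]; multiplied by ``ratio_scale`` (default 100) it is compared against
    the decision boundaries {-10, -2.5, 2.5, 10} separating hard-left, left,
    straight, right and hard-right.  A dominant left population steers left
    (negative angle).  Zero total activity decodes as straight.
    """
    cfg = cfg or LaneConfig()
    a = act.a
    if len(a) % 2:
        raise ValueError("need an even number of motor neurons")
    half = len(a) // 2
    a_left, a_right = float(a[:half].sum()), float(a[half:].sum())
    total = a_left + a_right
    ratio = 0.0 if total == 0.0 else cfg.ratio_scale * (a_left - a_right) / total
    # positive ratio = left population dominant = steer left (negative angle):
    # walk the boundaries with the angle list reversed.
    angles = list(cfg.angles)[::-1]
    idx = sum(ratio > b for b in cfg.boundaries)
    return float(angles[idx])


def smooth_reward(r_raw: float, r_smooth: float, dt: float, tau_r: float) -> float:
    """First-order exponential smoothing of the reward stream.

    ``r_smooth += (dt/tau_r) * (r_raw - r_smooth)``; preserves non-negativity
    whenever ``dt <= tau_r``.
    """
    if tau_r <= 0 or dt <= 0:
        raise ValueError("tau_r and dt must be positive")
    return r_smooth + (dt / tau_r) * (r_raw - r_smooth)
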