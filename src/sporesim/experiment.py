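"""Closed-loop orchestration, metrics and analysis.

The runner advances the whole system on two time grids: every millisecond the
world is rendered, events are encoded to spikes, the network fires, the fast
synaptic traces (PSP, eligibility, reward gradient) integrate one Euler step
with the smoothed global reward, motor activities are decoded to a command and
the environment moves; every 100 ms the synaptic parameters take one Langevin
step and the weights are re-projected; every 10 simulated minutes the learning
rate anneals.  Everything is reproducible from a single seed: one seed
sequence spawns independent streams for network construction, environment
resets, per-step spike draws and slow-update noise.

Two engines produce identical trajectories for the reaching task: a plain
NumPy reference loop (readable, used for short runs and cross-checking) and a
compiled kernel (:mod:`sporesim.fastloop`) for the long desk-scale runs.  The
lane task runs on the reference path only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .codecs import MotorActivity, decode_steering, lowpass_activity, motor_angles, smooth_reward
from .config import ExperimentConfig, config_hash
from .environments import LaneEnv, ReachingEnv, lane_errors, lane_reward, render_reaching
from .network import NetworkTopology, build_lane_network, build_reaching_network, step_network
from .plasticity import AnnealSchedule, anneal_learning_rate
from .vision import DVSSimulator, encode_lane_rates, AddressEvent

__all__ = [
    "MetricsLog",
    "run_closed_loop",
    "reach_rate",
    "weak_weight_count",
    "active_fraction",
    "policy_map",
    "reduced_reaching_config",
]


@dataclass
class MetricsLog:
    """Time-stamped reward trace, reset events and periodic weight snapshots."""

    t: np.ndarray  # fast-step time stamps, s
    reward: np.ndarray  # raw instantaneous reward per fast step
    reset_times: np.ndarray  # times at which the environment reset
    snapshot_times: np.ndarray
    snapshots: list[np.ndarray]  # flat weight arrays, one per snapshot time
    duration: float
    seed: int
    config_hash: str = ""
    n_slow_updates: int = 0
    final_beta: float = 0.0

    def snapshot_at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.snapshot_times - t)))
        return self.snapshots[idx]


def reduced_reaching_config(seed: int = 0, plastic: bool = True,
                            duration: float = 1800.0) -> ExperimentConfig:
    """Desk-scale reaching benchmark: 8x8 sensor, 4 motors, 2-fold multiplicity.

    The learning rate is raised to 1e-3 and the prior left flat (c_p = 0) so
    that learning effects are measurable within half an hour of simulated time
    on one CPU; ``plastic=False`` freezes the initial weights, giving the
    random-policy baseline at identical architecture and drive.

    The operating point differs from the full-scale defaults in three plumbing
    constants, chosen so the small network sits in the sensitive range of the
    exponential rate function rather than pinned at the cap: a wider potential
    scale (``delta_u = 2``), a gentler exploration drive onto the motor layer
    (0.2 instead of 10) and a velocity gain of 2.5 m/s per unit activity so
    the ball crosses the plane in tens of seconds (its diffusive transport
    scales with command speed, and the reach rate vanishes for both learner
    and baseline if transport is too slow to revisit the center at all).
    """
    cfg = ExperimentConfig(task="reaching", duration=duration, seed=seed, plastic=plastic)
    cfg.reaching = replace(cfg.reaching, pixels=8, n_motor=4, multiplicity=2,
                           exploration_to_motor=0.2, velocity_gain=2.5)
    cfg.network = replace(cfg.network, delta_u=2.0)
    cfg.spore = replace(cfg.spore, beta0=1e-3, c_p=0.0)
    cfg.annealing = False
    return cfg


# --------------------------------------------------------------------------- #
# Closed-loop runner
# --------------------------------------------------------------------------- #

def run_closed_loop(cfg: ExperimentConfig, engine: str = "auto") -> MetricsLog:
    """Run one experiment and return its metrics log.

    ``engine`` is ``"fast"`` (compiled kernel), ``"reference"`` (plain NumPy)
    or ``"auto"`` (fast for reaching, reference for lane).  Both engines
    consume the same pre-drawn random streams, so they produce matching
    trajectories.
    """
    if engine == "auto":
        engine = "fast" if cfg.task == "reaching" else "reference"
    if cfg.task == "lane" and engine == "fast":
        raise ValueError("the compiled kernel supports the reaching task only")
    if cfg.task == "reaching":
        return _run_reaching(cfg, engine)
    return _run_lane(cfg)


def _seed_streams(cfg: ExperimentConfig):
    ss = np.random.SeedSequence(cfg.seed)
    s_build, s_env, s_loop, s_slow = ss.spawn(4)
    return (np.random.default_rng(s_build), np.random.default_rng(s_env),
            np.random.default_rng(s_loop), np.random.default_rng(s_slow))


def _reset_pool(rng: np.random.Generator, cfg, n_pool: int) -> np.ndarray:
    """Pre-draw uniformly random ball positions outside the target disc."""
    limit = cfg.plane_half - cfg.ball_radius
    pool = np.empty((n_pool, 2))
    filled = 0
    while filled < n_pool:
        cand = rng.uniform(-limit, limit, size=(2 * (n_pool - filled), 2))
        good = cand[(cand ** 2).sum(axis=1) > cfg.target_radius ** 2]
        take = min(len(good), n_pool - filled)
        pool[filled:filled + take] = good[:take]
        filled += take
    return pool


def _spike_prob(u: float, neuron, dt: float) -> float:
    u_cap = neuron.delta_u * math.log(neuron.rho_max / neuron.rho0)
    rho = neuron.rho0 * math.exp(min(u, u_cap) / neuron.delta_u)
    return 1.0 - math.exp(-rho * dt), rho


def _run_reaching(cfg: ExperimentConfig, engine: str) -> MetricsLog:
    sp, rc, nc, cd = cfg.spore, cfg.reaching, cfg.network, cfg.codec
    rng_build, rng_env, rng_loop, rng_slow = _seed_streams(cfg)
    top = build_reaching_network(rc, sp, nc, rng_build)
    group = top.plastic

    steps_per_slow = sp.steps_per_slow
    n_slow = int(round(cfg.duration / sp.dt_slow))
    total_steps = n_slow * steps_per_slow
    n_pool = max(64, int(2 * cfg.duration) + 8)
    pool = _reset_pool(rng_env, rc, n_pool)
    ball = pool[0].copy()
    pool_idx = np.array([1], dtype=np.int64)

    n = rc.pixels
    pixel_size = 2.0 * rc.plane_half / n
    centers = -rc.plane_half + (np.arange(n) + 0.5) * pixel_size
    centers_row = centers[::-1].copy()  # image row 0 = top of the plane
    ref = render_reaching(_BallState(ball), rc).pixels  # primed sensor reference
    ang = motor_angles(rc.n_motor)
    cosb, sinb = np.cos(ang), np.sin(ang)

    y_in = np.zeros(top.n_inputs)
    a = np.zeros(rc.n_motor)
    scalars = np.zeros(3)  # y_noise, y_exp, r_smooth
    rewards = np.empty(total_steps)
    resets = np.zeros(total_steps, dtype=np.int8)

    sched = AnnealSchedule(beta=sp.beta0)
    snap_times, snaps = [0.0], [group.w.ravel().copy()]
    next_snap = cfg.snapshot_interval

    if engine == "fast":
        from . import fastloop
        chunk_fn = fastloop.reaching_chunk
    else:
        chunk_fn = _reaching_chunk_reference

    consts = dict(
        dt=sp.dt_fast, limit=rc.plane_half - rc.ball_radius,
        target_r2=rc.target_radius ** 2, ball_radius=rc.ball_radius,
        pixel_size=pixel_size, threshold=cfg.vision.threshold,
        decay_psp=1.0 - sp.dt_fast / sp.tau_psp,
        decay_a=math.exp(-sp.dt_fast / cd.tau_activity),
        inv_tau_e=1.0 / sp.tau_e, inv_tau_g=1.0 / sp.tau_g,
        tau_r=cd.tau_reward, rho0=nc.rho0, delta_u=nc.delta_u,
        u_cap=nc.delta_u * math.log(nc.rho_max / nc.rho0),
        p_noise=1.0 - math.exp(-rc.noise_rate * sp.dt_fast),
        w_noise=rc.noise_to_exploration, w_exp_motor=rc.exploration_to_motor,
        v_gain=rc.velocity_gain, v_lim=rc.v_lim, beta_lim=rc.beta_lim,
        r_coef=rc.reward_coef, r_exp=rc.reward_exp,
    )

    for k in range(n_slow):
        uniforms = rng_loop.random((steps_per_slow, 2 + rc.n_motor))
        w_eff = group.w.sum(axis=2)
        chunk_fn(
            steps_per_slow, ball, ref, centers, centers_row, top.w_vis_to_exp,
            y_in, scalars, w_eff, group.w, group.e, group.g, a, cosb, sinb,
            uniforms, pool, pool_idx,
            rewards[k * steps_per_slow:(k + 1) * steps_per_slow],
            resets[k * steps_per_slow:(k + 1) * steps_per_slow],
            cfg.plastic, **consts,
        )
        t_now = (k + 1) * sp.dt_slow
        if cfg.plastic:
            group.slow_step(sched.beta, rng_slow.standard_normal(group.w.shape))
            if cfg.annealing:
                sched = anneal_learning_rate(sched, t_now, sp)
        if t_now >= next_snap - 1e-9:
            snap_times.append(t_now)
            snaps.append(group.w.ravel().copy())
            next_snap += cfg.snapshot_interval

    if not snap_times or snap_times[-1] < cfg.duration - 1e-9:
        snap_times.append(cfg.duration)
        snaps.append(group.w.ravel().copy())

    t = (np.arange(total_steps) + 1) * sp.dt_fast
    return MetricsLog(
        t=t, reward=rewards, reset_times=t[resets.astype(bool)],
        snapshot_times=np.asarray(snap_times), snapshots=snaps,
        duration=cfg.duration, seed=cfg.seed, config_hash=config_hash(cfg),
        n_slow_updates=n_slow if cfg.plastic else 0, final_beta=sched.beta,
    )


class _BallState:
    """Minimal stand-in for ReachingState used by the renderer."""

    def __init__(self, pos: np.ndarray):
        self.ball_pos = pos


def _reaching_chunk_reference(steps, ball, ref, centers, centers_row, w_inh,
                              y_in, scalars, w_eff, w3, e3, g3, a, cosb, sinb,
                              uniforms, pool, pool_idx, rewards, resets, plastic,
                              *, dt, limit, target_r2, ball_radius, pixel_size,
                              threshold, decay_psp, decay_a, inv_tau_e, inv_tau_g,
                              tau_r, rho0, delta_u, u_cap, p_noise, w_noise,
                              w_exp_motor, v_gain, v_lim, beta_lim, r_coef, r_exp):
    """Plain-NumPy mirror of the compiled reaching kernel (one 100 ms chunk).

    Consumes the same pre-drawn uniforms in the same order, so fast and
    reference engines produce matching trajectories.
    """
    n = len(centers)
    n_vis = n * n
    n_motor = len(a)
    for k in range(steps):
        # render and event-camera step
        dx = centers[None, :] - ball[0]
        dy = centers_row[:, None] - ball[1]
        frame = np.clip((np.hypot(dx, dy) - ball_radius) / pixel_size + 0.5, 0.0, 1.0)
        mask = np.abs(frame - ref) > threshold
        ref[mask] = frame[mask]
        counts = np.concatenate([mask.ravel(), mask.sum(axis=1), mask.sum(axis=0)])
        # input traces, exploration chain, motor layer
        y_in *= decay_psp
        y_in += counts
        noise_spike = uniforms[k, 0] < p_noise
        scalars[0] = scalars[0] * decay_psp + float(noise_spike)
        u_exp = w_noise * scalars[0] + float(np.dot(w_inh, y_in[:n_vis]))
        rho_exp = rho0 * math.exp(min(u_exp, u_cap) / delta_u)
        exp_spike = uniforms[k, 1] < 1.0 - math.exp(-rho_exp * dt)
        scalars[1] = scalars[1] * decay_psp + float(exp_spike)
        u = w_eff.T @ y_in + w_exp_motor * scalars[1]
        rho = rho0 * np.exp(np.minimum(u, u_cap) / delta_u)
        p_spike = 1.0 - np.exp(-rho * dt)
        spikes = uniforms[k, 2:2 + n_motor] < p_spike
        # fast plasticity traces with the smoothed global reward; the rate
        # compensator is the effective per-step intensity p/dt of the sampled
        # Bernoulli process, so the spike term is exactly mean-zero
        if plastic:
            dz = spikes.astype(float) - p_spike
            e3 += dt * (-e3 * inv_tau_e) + w3 * y_in[:, None, None] * dz[None, :, None]
            g3 += dt * (-g3 * inv_tau_g + scalars[2] * e3)
        # decode, reward, environment
        a *= decay_a
        a += spikes
        vx = v_gain * float(np.dot(cosb, a))
        vy = v_gain * float(np.dot(sinb, a))
        speed = math.hypot(vx, vy)
        reward = 0.0
        if speed > v_lim:
            gx, gy = -ball[0], -ball[1]
            gnorm = math.hypot(gx, gy)
            r_beta = 0.0
            if gnorm >= 1e-12:
                cosang = max(-1.0, min(1.0, (vx * gx + vy * gy) / (speed * gnorm)))
                berr = math.acos(cosang)
                r_beta = 1.0 - berr / beta_lim if berr < beta_lim else 0.0
            reward = r_coef * speed * (r_beta + 1.0) ** r_exp
        ball[0] = min(max(ball[0] + vx * dt, -limit), limit)
        ball[1] = min(max(ball[1] + vy * dt, -limit), limit)
        if ball[0] * ball[0] + ball[1] * ball[1] <= target_r2:
            ball[:] = pool[pool_idx[0] % len(pool)]
            pool_idx[0] += 1
            resets[k] = 1
        rewards[k] = reward
        scalars[2] += (dt / tau_r) * (reward - scalars[2])


def _run_lane(cfg: ExperimentConfig) -> MetricsLog:
    sp, lc, nc, cd = cfg.spore, cfg.lane, cfg.network, cfg.codec
    rng_build, _rng_env, rng_loop, rng_slow = _seed_streams(cfg)
    top = build_lane_network(lc, sp, nc, rng_build)
    group = top.plastic
    env = LaneEnv(lc)
    dvs = DVSSimulator((lc.height, lc.width), cfg.vision.threshold)
    dvs.step_masks(env.render().pixels)  # prime the reference frame

    steps_per_slow = sp.steps_per_slow
    n_slow = int(round(cfg.duration / sp.dt_slow))
    total_steps = n_slow * steps_per_slow
    nx, ny = lc.width // lc.window, lc.height // lc.window
    act = MotorActivity(a=np.zeros(lc.n_motor), tau=cd.tau_activity)
    r_smooth = 0.0
    rewards = np.empty(total_steps)
    resets = np.zeros(total_steps, dtype=np.int8)
    sched = AnnealSchedule(beta=sp.beta0)
    snap_times, snaps = [0.0], [group.w.ravel().copy()]
    next_snap = cfg.snapshot_interval
    dt = sp.dt_fast

    for k in range(n_slow):
        for j in range(steps_per_slow):
            step = k * steps_per_slow + j
            mask = dvs.step_masks(env.render().pixels)
            win_counts = mask.reshape(ny, lc.window, nx, lc.window).sum(axis=(1, 3))
            in_rates = np.minimum(cfg.vision.lane_gain * win_counts.ravel(), nc.rho_max)
            in_spikes = rng_loop.random(in_rates.shape) < 1.0 - np.exp(-in_rates * dt)
            spikes, rates = step_network(top, in_spikes.astype(float), dt, rng_loop)
            if cfg.plastic:
                # effective rate of the sampled Bernoulli process (mean-zero spike term)
                rho_eff = (1.0 - np.exp(-rates * dt)) / dt
                group.fast_step(top.y_in[:, None, None],
                                spikes.astype(float)[None, :, None],
                                rho_eff[None, :, None], r_smooth)
            act = lowpass_activity(act, spikes, dt)
            steering = decode_steering(act, lc)
            reward, reset = env.step(steering, dt)
            rewards[step] = reward
            resets[step] = reset
            r_smooth = smooth_reward(reward, r_smooth, dt, cd.tau_reward)
        t_now = (k + 1) * sp.dt_slow
        if cfg.plastic:
            group.slow_step(sched.beta, rng_slow.standard_normal(group.w.shape))
            if cfg.annealing:
                sched = anneal_learning_rate(sched, t_now, sp)
        if t_now >= next_snap - 1e-9:
            snap_times.append(t_now)
            snaps.append(group.w.ravel().copy())
            next_snap += cfg.snapshot_interval

    if not snap_times or snap_times[-1] < cfg.duration - 1e-9:
        snap_times.append(cfg.duration)
        snaps.append(group.w.ravel().copy())

    t = (np.arange(total_steps) + 1) * sp.dt_fast
    return MetricsLog(
        t=t, reward=rewards, reset_times=t[resets.astype(bool)],
        snapshot_times=np.asarray(snap_times), snapshots=snaps,
        duration=cfg.duration, seed=cfg.seed, config_hash=config_hash(cfg),
        n_slow_updates=n_slow if cfg.plastic else 0, final_beta=sched.beta,
    )


# --------------------------------------------------------------------------- #
# Metrics
# --------------------------------------------------------------------------- #

def reach_rate(log: MetricsLog, window: float = 250.0) -> np.ndarray:
    """Reset (= goal-reach) counts per tiled half-open window [k*w, (k+1)*w).

    The final window may be partial; a reset falling exactly on a boundary is
    assigned to the later window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = max(1, int(math.ceil(log.duration / window))) if log.duration > 0 else 1
    counts = np.zeros(n_windows, dtype=int)
    for t in log.reset_times:
        counts[min(int(t // window), n_windows - 1)] += 1
    return counts


def weak_weight_count(weights: np.ndarray, threshold: float = 0.07) -> int:
    """Number of synaptic weights strictly below the retraction threshold."""
    weights = np.asarray(weights)
    if weights.size == 0:
        raise ValueError("empty weight snapshot")
    return int((weights < threshold).sum())


def active_fraction(total: int, weak: int) -> int:
    """Percentage of synapses above the weak-weight threshold, nearest integer."""
    if total <= 0 or weak < 0 or weak > total:
        raise ValueError("need 0 <= weak <= total, total > 0")
    return int(round(100.0 * (total - weak) / total))


def policy_map(weights: np.ndarray, top: NetworkTopology,
               velocity_gain: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel command vectors and their angular correctness for a reaching network.

    For pixel p, the vector is the motor-population readout of one event at p:
    the sum over motor neurons of (pixel + row-axis + column-axis) effective
    weights times the neuron's preferred direction.  Correctness is the cosine
    of the angle between that vector and the direction from the pixel toward
    the plane center (NaN where either vector is null, e.g. at the exact
    center).  Returns ``(vectors[n, n, 2], correctness[n, n])``.
    """
    if top.task != "reaching":
        raise ValueError("policy maps are defined for the reaching topology")
    n = int(math.isqrt(top.n_visual))
    w = np.asarray(weights, dtype=float).reshape(top.n_inputs, top.n_motor, top.multiplicity)
    w_eff = w.sum(axis=2)
    ang = motor_angles(top.n_motor)
    units = np.stack([np.cos(ang), np.sin(ang)], axis=1)  # (n_motor, 2)
    w_pix = w_eff[: n * n].reshape(n, n, top.n_motor)
    w_row = w_eff[n * n: n * n + n]  # (n, n_motor)
    w_col = w_eff[n * n + n:]
    combined = w_pix + w_row[:, None, :] + w_col[None, :, :]
    vectors = velocity_gain * combined @ units  # (n, n, 2)

    # direction from each pixel's plane position toward the center (origin)
    half = n / 2.0
    px = (np.arange(n) + 0.5) - half  # plane x in pixel units
    py = half - (np.arange(n) + 0.5)  # plane y; image row 0 is the top
    to_center = np.stack(np.broadcast_arrays(-px[None, :], -py[:, None]), axis=2).astype(float)
    vnorm = np.linalg.norm(vectors, axis=2)
    cnorm = np.linalg.norm(to_center, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        correctness = (vectors * to_center).sum(axis=2) / (vnorm * cnorm)
    correctness[(vnorm == 0) | (cnorm == 0)] = np.nan
    return vectors, correctness
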