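"""The two closed-loop worlds: ball reaching and lane following.

Reaching: a ball of 2 m radius moves under instantaneous velocity commands on
a 20 x 20 m walled plane and must reach the 2 m target disc at the center,
observed by a top-down camera.  Reward is directional: positive only when the
ball moves toward the goal within an angular tolerance at sufficient speed.
Reaching the center teleports the ball to a random position; the reset is
never signaled to the learner (no episode boundary exists).

Lane following: a vehicle drives at constant speed on the right lane of a
closed circuit (a rounded rectangle here), steered by discrete angle commands
through a kinematic bicycle model, observed by a forward camera.  Reward is a
product of Gaussians in the heading error (degrees) and the lateral offset
from the lane center (meters), calibrated to halve per 5 degrees or 0.1 m.
Leaving the lane resets the vehicle to its fixed start pose, again unsignaled.

Both rewards are non-negative everywhere, as the sampling rule's derivation
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import LaneConfig, ReachingConfig
from .vision import IntensityFrame

__all__ = [
    "ReachingState",
    "ReachingEnv",
    "reaching_step",
    "reaching_reward",
    "render_reaching",
    "TrackGeometry",
    "LaneState",
    "LaneEnv",
    "lane_errors",
    "lane_reward",
    "lane_step",
    "render_lane",
]


# --------------------------------------------------------------------------- #
# Reaching
# --------------------------------------------------------------------------- #

@dataclass
class ReachingState:
    """Ball pose on the walled plane; the target disc sits at the origin."""

    ball_pos: np.ndarray = field(default_factory=lambda: np.array([5.0, 5.0]))


def reaching_step(state: ReachingState, v_cmd, dt: float, rng: np.random.Generator,
                  cfg: ReachingConfig) -> tuple[ReachingState, bool]:
    """Integrate the ball one step; teleport to a random position on goal contact.

    The ball center is clamped so the ball stays inside the walls.  If after the
    move the center lies within the target disc, the ball is reset uniformly at
    random on the plane (outside the target, so a reset position never triggers
    an immediate second reset).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    limit = cfg.plane_half - cfg.ball_radius
    pos = np.clip(state.ball_pos + np.asarray(v_cmd, dtype=float) * dt, -limit, limit)
    reset = bool(pos @ pos <= cfg.target_radius ** 2)
    if reset:
        while True:
            pos = rng.uniform(-limit, limit, size=2)
            if pos @ pos > cfg.target_radius ** 2:
                break
    return ReachingState(ball_pos=pos), reset


def reaching_reward(state: ReachingState, v_cmd, cfg: ReachingConfig) -> float:
    """Directional reward ``c * r_v * (r_beta + 1)^p``.

    ``r_beta = 1 - beta_err/beta_lim`` when the angle ``beta_err`` between the
    commanded motion and the straight line to the goal is below ``beta_lim``
    (else 0), and ``r_v = |v|`` when the speed exceeds ``v_lim`` (else 0, which
    zeroes the whole reward).  Always non-negative.
    """
    v = np.asarray(v_cmd, dtype=float)
    speed = float(np.hypot(v[0], v[1]))
    if speed <= cfg.v_lim:
        return 0.0
    goal = -state.ball_pos
    gnorm = float(np.hypot(goal[0], goal[1]))
    if gnorm < 1e-12:
        r_beta = 0.0
    else:
        cosang = float(np.clip((v @ goal) / (speed * gnorm), -1.0, 1.0))
        beta_err = math.acos(cosang)
        r_beta = 1.0 - beta_err / cfg.beta_lim if beta_err < cfg.beta_lim else 0.0
    return cfg.reward_coef * speed * (r_beta + 1.0) ** cfg.reward_exp


def render_reaching(state: ReachingState, cfg: ReachingConfig, t: float = 0.0) -> IntensityFrame:
    """Top-down view: dark ball disc on a light plane, soft one-pixel edge.

    The soft edge makes pixel intensities vary continuously with sub-pixel
    ball motion, so the event camera responds to slow movement once the
    accumulated change crosses its threshold.
    """
    n = cfg.pixels
    pixel_size = 2.0 * cfg.plane_half / n
    centers = -cfg.plane_half + (np.arange(n) + 0.5) * pixel_size
    dx = centers[None, :] - state.ball_pos[0]
    # image row 0 is the top of the plane (+y)
    dy = centers[::-1, None] - state.ball_pos[1]
    dist = np.hypot(dx, dy)
    pixels = np.clip((dist - cfg.ball_radius) / pixel_size + 0.5, 0.0, 1.0)
    return IntensityFrame(pixels=pixels, t=t)


class ReachingEnv:
    """Thin stateful wrapper bundling step, reward and rendering."""

    def __init__(self, cfg: ReachingConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        limit = cfg.plane_half - cfg.ball_radius
        while True:
            pos = rng.uniform(-limit, limit, size=2)
            if pos @ pos > cfg.target_radius ** 2:
                break
        self.state = ReachingState(ball_pos=pos)

    def step(self, v_cmd, dt: float) -> tuple[float, bool]:
        reward = reaching_reward(self.state, v_cmd, self.cfg)
        self.state, reset = reaching_step(self.state, v_cmd, dt, self.rng, self.cfg)
        return reward, reset

    def render(self, t: float = 0.0) -> IntensityFrame:
        return render_reaching(self.state, self.cfg, t=t)


# --------------------------------------------------------------------------- #
# Lane following
# --------------------------------------------------------------------------- #

class TrackGeometry:
    """Closed rounded-rectangle centerline of the right lane, with nearest-point query.

    The curve is a counter-clockwise sequence of four straights and four
    quarter-circle corners, parameterized by arc length.  ``nearest`` returns
    the closest centerline point, its tangent heading and the distance; exact
    ties between branches are broken by the smaller arc length.
    """

    def __init__(self, length: float = 10.0, width: float = 6.0, corner_radius: float = 2.0):
        hx, hy, rc = length / 2.0, width / 2.0, corner_radius
        if rc <= 0 or rc > min(hx, hy):
            raise ValueError("corner radius must be positive and fit the rectangle")
        self._segments: list[dict] = []
        s = 0.0
        straight_x, straight_y = length - 2 * rc, width - 2 * rc

        def add_straight(p0, angle, seg_len):
            nonlocal s
            self._segments.append(dict(kind="straight", s0=s, length=seg_len,
                                       p0=np.array(p0, dtype=float), angle=angle))
            s += seg_len

        def add_arc(center, a0, seg_len):
            nonlocal s
            self._segments.append(dict(kind="arc", s0=s, length=seg_len,
                                       center=np.array(center, dtype=float), a0=a0, r=rc))
            s += seg_len

        arc_len = math.pi * rc / 2.0
        add_straight((-(hx - rc), -hy), 0.0, straight_x)
        add_arc((hx - rc, -(hy - rc)), -math.pi / 2.0, arc_len)
        add_straight((hx, -(hy - rc)), math.pi / 2.0, straight_y)
        add_arc((hx - rc, hy - rc), 0.0, arc_len)
        add_straight((hx - rc, hy), math.pi, straight_x)
        add_arc((-(hx - rc), hy - rc), math.pi / 2.0, arc_len)
        add_straight((-hx, hy - rc), -math.pi / 2.0, straight_y)
        add_arc((-(hx - rc), -(hy - rc)), math.pi, arc_len)
        self.total_length = s

    def point_at(self, s: float) -> tuple[np.ndarray, float]:
        """Position and tangent heading (rad) at arc length ``s`` (wraps around)."""
        s = s % self.total_length
        for seg in self._segments:
            ds = s - seg["s0"]
            if ds <= seg["length"] + 1e-12:
                if seg["kind"] == "straight":
                    d = np.array([math.cos(seg["angle"]), math.sin(seg["angle"])])
                    return seg["p0"] + ds * d, seg["angle"]
                ang = seg["a0"] + ds / seg["r"]
                pos = seg["center"] + seg["r"] * np.array([math.cos(ang), math.sin(ang)])
                return pos, ang + math.pi / 2.0  # CCW tangent
        raise AssertionError("arc length out of range")  # pragma: no cover

    def nearest(self, p) -> tuple[float, np.ndarray, float, float]:
        """(arc length, point, tangent heading, distance) of the closest centerline point."""
        p = np.asarray(p, dtype=float)
        best: tuple[float, np.ndarray, float, float] | None = None
        for seg in self._segments:
            if seg["kind"] == "straight":
                d = np.array([math.cos(seg["angle"]), math.sin(seg["angle"])])
                ds = float(np.clip((p - seg["p0"]) @ d, 0.0, seg["length"]))
                q = seg["p0"] + ds * d
                heading = seg["angle"]
            else:
                rel = p - seg["center"]
                ang = math.atan2(rel[1], rel[0])
                ds = float(np.clip(((ang - seg["a0"]) % (2 * math.pi)) * seg["r"],
                                   0.0, seg["length"]))
                ang_c = seg["a0"] + ds / seg["r"]
                q = seg["center"] + seg["r"] * np.array([math.cos(ang_c), math.sin(ang_c)])
                heading = ang_c + math.pi / 2.0
            dist = float(np.hypot(*(p - q)))
            s_here = seg["s0"] + ds
            cand = (s_here, q, heading, dist)
            if best is None or dist < best[3] - 1e-12 or (
                    abs(dist - best[3]) <= 1e-12 and s_here < best[0]):
                best = cand
        assert best is not None
        return best


@dataclass
class LaneState:
    """Vehicle pose on the track; speed is constant by construction."""

    x: float
    y: float
    heading: float  # rad, world frame
    on_track: bool = True

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


def lane_errors(state: LaneState, track: TrackGeometry) -> tuple[float, float]:
    """(beta_err in degrees, d_err in meters), both non-negative.

    ``beta_err`` is the absolute wrapped angle between the vehicle heading and
    the lane tangent at the nearest centerline point; ``d_err`` is the distance
    to that point.
    """
    _, _, tangent, dist = track.nearest(state.pos)
    dpsi = (state.heading - tangent + math.pi) % (2 * math.pi) - math.pi
    return abs(math.degrees(dpsi)), dist


def lane_reward(beta_err: float, d_err: float, angle_coef: float = 0.03,
                dist_coef: float = 70.0) -> float:
    """Gaussian product reward in (0, 1]: ``exp(-0.03 beta^2) * exp(-70 d^2)``.

    ``beta_err`` in degrees, ``d_err`` in meters; the default coefficients
    halve the score per 5 degrees of heading error or 0.1 m of offset
    (``exp(-0.75) ~ exp(-0.70) ~ 1/2``).
    """
    if beta_err < 0 or d_err < 0:
        raise ValueError("errors must be non-negative")
    return math.exp(-angle_coef * beta_err ** 2) * math.exp(-dist_coef * d_err ** 2)


def lane_step(state: LaneState, steering_deg: float, dt: float, track: TrackGeometry,
              cfg: LaneConfig) -> tuple[LaneState, bool]:
    """Kinematic bicycle step at constant speed; reset to start when off-track.

    Heading rate is ``(speed / wheelbase) * tan(steering)``; the vehicle is
    off-track when its lateral error exceeds the lane half-width, upon which
    the pose snaps back to the fixed start (no signal to the learner).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    heading = state.heading + (cfg.speed / cfg.wheelbase) * math.tan(
        math.radians(steering_deg)) * dt
    x = state.x + cfg.speed * math.cos(heading) * dt
    y = state.y + cfg.speed * math.sin(heading) * dt
    new = LaneState(x=x, y=y, heading=heading)
    _, d_err = lane_errors(new, track)
    if d_err > cfg.lane_halfwidth:
        start, start_heading = track.point_at(0.0)
        return LaneState(x=float(start[0]), y=float(start[1]),
                         heading=start_heading, on_track=True), True
    return new, False


def render_lane(state: LaneState, track: TrackGeometry, cfg: LaneConfig,
                t: float = 0.0) -> IntensityFrame:
    """Forward pinhole view of the two lane-boundary lines, dark on light.

    Points are sampled densely along both boundaries (centerline offset by
    ±lane half-width) over ``lookahead`` meters ahead of the vehicle, projected
    through a pitched pinhole camera at ``cam_height`` above the ground, and
    rasterized as dark pixels.
    """
    s_v, _, _, _ = track.nearest(state.pos)
    n_samples = max(int(cfg.lookahead / 0.05), 2)
    svals = s_v + np.linspace(0.0, cfg.lookahead, n_samples)
    pts, normals = [], []
    for s in svals:
        q, tangent = track.point_at(float(s))
        pts.append(q)
        normals.append((-math.sin(tangent), math.cos(tangent)))
    pts = np.asarray(pts)
    normals = np.asarray(normals)
    boundary_pts = np.concatenate([pts + cfg.lane_halfwidth * normals,
                                   pts - cfg.lane_halfwidth * normals])

    rel = boundary_pts - state.pos
    ch, sh = math.cos(state.heading), math.sin(state.heading)
    xf = rel @ np.array([ch, sh])  # forward
    yl = rel @ np.array([-sh, ch])  # left
    cp, sp = math.cos(cfg.cam_pitch), math.sin(cfg.cam_pitch)
    depth = xf * cp + cfg.cam_height * sp
    zi = -cfg.cam_height * cp + xf * sp  # image-up component (negative: ground)
    visible = depth > 0.1
    col = np.round(cfg.width / 2.0 - cfg.focal * yl[visible] / depth[visible]).astype(int)
    row = np.round(cfg.height / 2.0 - cfg.focal * zi[visible] / depth[visible]).astype(int)
    pixels = np.ones((cfg.height, cfg.width))
    keep = (col >= 0) & (col < cfg.width) & (row >= 0) & (row < cfg.height)
    pixels[row[keep], col[keep]] = 0.0
    return IntensityFrame(pixels=pixels, t=t)


class LaneEnv:
    """Thin stateful wrapper bundling step, errors, reward and rendering."""

    def __init__(self, cfg: LaneConfig):
        self.cfg = cfg
        self.track = TrackGeometry(cfg.track_length, cfg.track_width, cfg.corner_radius)
        start, heading = self.track.point_at(0.0)
        self.start_pose = (float(start[0]), float(start[1]), heading)
        self.state = LaneState(x=self.start_pose[0], y=self.start_pose[1],
                               heading=self.start_pose[2])

    def step(self, steering_deg: float, dt: float) -> tuple[float, bool]:
        beta_err, d_err = lane_errors(self.state, self.track)
        reward = lane_reward(beta_err, d_err, self.cfg.angle_coef, self.cfg.dist_coef)
        self.state, reset = lane_step(self.state, steering_deg, dt, self.track, self.cfg)
        return reward, reset

    def render(self, t: float = 0.0) -> IntensityFrame:
        return render_lane(self.state, self.track, self.cfg, t=t)
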