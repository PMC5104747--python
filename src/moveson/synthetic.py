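"""Synthetic trajectories and cohort-structured feature tables.

The study's motion-capture recordings are not deposited, so every stage of
the pipeline is exercised on generated data with known ground truth:

* :func:`gen_trajectory` emulates a child's head marker moving inside the
  4.66 x 5.40 m tracked area at 180 fps, in one of five styles.  The
  analytic styles (``straight``, ``circle``, ``square``) have closed-form
  kinematics for oracle tests; ``smooth`` integrates a low-passed
  Ornstein-Uhlenbeck velocity process (wandering but lawful movement);
  ``jerky`` uses piecewise-constant headings with Poisson-timed abrupt
  turns, Bernoulli full stops, and per-frame speed jitter (choppy,
  stop-and-go movement).
* :func:`gen_cohort` draws per-observation feature values from the
  three-level random-intercept model (observations within participants
  within groups) with configurable fixed effects and variance components,
  returning the table together with its generating truth.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import AREA_WIDTH, AREA_HEIGHT
from .trajectory_io import Trajectory

__all__ = ["MovementStyleParams", "CohortSimParams", "gen_trajectory", "gen_cohort"]

STYLES = ("smooth", "jerky", "straight", "circle", "square")


@dataclass(frozen=True)
class MovementStyleParams:
    """Parameters of one synthetic movement style.

    mean_speed is the target time-averaged speed in m/s (pauses included);
    turn_rate is the expected number of abrupt heading changes per second
    (jerky); pause_prob the per-second probability of entering a full stop
    (jerky; stops render speed exactly 0 so silence-at-rest is exercised
    end to end); smoothing_time the velocity low-pass time constant in
    seconds (smooth).
    """

    style: str = "smooth"
    mean_speed: float = 0.15
    turn_rate: float = 1.5
    pause_prob: float = 0.15
    pause_duration: float = 0.5
    speed_jitter: float = 0.25
    heading_jitter: float = 0.6
    smoothing_time: float = 6.0
    radius: float = 0.8
    side: float = 2.0
    area: tuple[float, float] = (AREA_WIDTH, AREA_HEIGHT)
    duration: float = 25.0
    rate: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}; choose from {STYLES}")
        if self.mean_speed < 0 or self.duration <= 0 or self.rate <= 0:
            raise ValueError("mean_speed >= 0 and positive duration/rate required")
        if self.area[0] <= 0 or self.area[1] <= 0:
            raise ValueError("area must be positive")


def _reflect(p: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by specular reflection."""
    width = hi - lo
    if width <= 0:
        return lo
    q = (p - lo) % (2 * width)
    return lo + (q if q <= width else 2 * width - q)


def _integrate_with_reflection(vx, vy, dt, area):
    """Cumulate velocity into positions, reflecting at the area walls.

    Reflection flips the corresponding velocity component so kinematics
    stay stationary and the marker never sticks to a wall.
    """
    hw, hh = area[0] / 2.0, area[1] / 2.0
    n = len(vx) + 1
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = 0.0, 0.0
    vx = vx.copy()
    vy = vy.copy()
    sx, sy = 1.0, 1.0
    for i in range(1, n):
        px = x[i - 1] + sx * vx[i - 1] * dt
        py = y[i - 1] + sy * vy[i - 1] * dt
        if not -hw <= px <= hw:
            sx = -sx
            px = _reflect(px, -hw, hw)
        if not -hh <= py <= hh:
            sy = -sy
            py = _reflect(py, -hh, hh)
        x[i], y[i] = px, py
    return x, y


def _ou(n: int, dt: float, tau: float, sigma: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (mean 0, stationary SD sigma)."""
    a = np.exp(-dt / tau)
    drive = sigma * np.sqrt(1.0 - a * a)
    z = np.empty(n)
    z[0] = rng.normal(0.0, sigma)
    eta = rng.normal(size=n - 1)
    for i in range(1, n):
        z[i] = a * z[i - 1] + drive * eta[i - 1]
    return z


def _smooth_velocity(n: int, dt: float, p: MovementStyleParams, rng) -> tuple:
    """Correlated random walk: slowly drifting heading, lognormal speed.

    Heading diffuses as a Wiener process whose variance grows by one
    radian^2 per smoothing_time seconds, so the path consists of sweeping
    arcs with persistence length ~ mean_speed * smoothing_time.  Speed is
    a smooth lognormal modulation (OU in the log, time constant
    smoothing_time, CV ~ 0.4) around mean_speed, rescaled so the realized
    time-average matches mean_speed exactly.
    """
    tau = max(p.smoothing_time, 10 * dt)
    heading = np.cumsum(
        np.concatenate(([rng.uniform(0, 2 * np.pi)],
                        rng.normal(0.0, np.sqrt(dt / tau), n - 1))))
    log_s = _ou(n, dt, tau, 0.4, rng)
    s = np.exp(log_s)
    s *= p.mean_speed / max(s.mean(), 1e-12)
    return s * np.cos(heading), s * np.sin(heading)


def _jerky_velocity(n: int, dt: float, p: MovementStyleParams, rng) -> tuple:
    """Piecewise-constant headings with abrupt turns, stops and jitter."""
    pause_frac = (p.pause_prob * p.pause_duration) / (
        1.0 + p.pause_prob * p.pause_duration)
    moving_speed = p.mean_speed / max(1.0 - pause_frac, 1e-9)
    heading = rng.uniform(0, 2 * np.pi)
    vx = np.empty(n)
    vy = np.empty(n)
    pause_left = 0.0
    for i in range(n):
        if pause_left > 0:
            vx[i] = vy[i] = 0.0
            pause_left -= dt
            continue
        if rng.random() < p.pause_prob * dt:
            pause_left = rng.exponential(p.pause_duration)
            vx[i] = vy[i] = 0.0
            continue
        if rng.random() < p.turn_rate * dt:
            heading = rng.uniform(0, 2 * np.pi)
        h = heading + p.heading_jitter * rng.normal() * np.sqrt(dt)
        s = moving_speed * max(1.0 + p.speed_jitter * rng.normal(), 0.05)
        vx[i] = s * np.cos(h)
        vy[i] = s * np.sin(h)
    return vx, vy


def gen_trajectory(params: MovementStyleParams) -> Trajectory:
    """Generate one synthetic head trajectory confined to the tracked area."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.rate)) + 1
    dt = 1.0 / p.rate
    t = np.arange(n) * dt

    if p.style == "straight":
        # monotone rectilinear path through the center, clipped to the area
        # diagonal so it never needs to reflect (keeps DI exactly 1)
        hw, hh = p.area[0] / 2, p.area[1] / 2
        direction = np.array([p.area[0], p.area[1]])
        direction = direction / np.hypot(*direction)
        half_span = min(hw / abs(direction[0]), hh / abs(direction[1]))
        path_len = p.mean_speed * p.duration
        if path_len > 2 * half_span:
            raise ValueError(
                "straight path longer than the area diagonal; lower "
                "mean_speed or duration")
        start = -direction * path_len / 2.0
        x = start[0] + direction[0] * p.mean_speed * t
        y = start[1] + direction[1] * p.mean_speed * t
    elif p.style == "circle":
        omega = p.mean_speed / p.radius
        x = p.radius * np.cos(omega * t)
        y = p.radius * np.sin(omega * t)
    elif p.style == "square":
        # perimeter of a side-length `side` square traversed at constant speed
        s = (p.mean_speed * t) % (4 * p.side)
        x = np.empty(n)
        y = np.empty(n)
        half = p.side / 2
        for i, si in enumerate(s):
            leg, u = divmod(si, p.side)
            if leg == 0:
                x[i], y[i] = -half + u, -half
            elif leg == 1:
                x[i], y[i] = half, -half + u
            elif leg == 2:
                x[i], y[i] = half - u, half
            else:
                x[i], y[i] = -half, half - u
    else:
        if p.style == "smooth":
            vx, vy = _smooth_velocity(n - 1, dt, p, rng)
        else:
            vx, vy = _jerky_velocity(n - 1, dt, p, rng)
        x, y = _integrate_with_reflection(vx, vy, dt, p.area)

    return Trajectory(t=t, x=x, y=y, rate=p.rate,
                      marker_id=f"synthetic-{p.style}")


@dataclass(frozen=True)
class CohortSimParams:
    """Three-level cohort simulator settings.

    Defaults mirror the study design (3 groups of ~4 children, two
    sessions, 12 observations per participant and sound model) and its
    estimated variance components for the normalized energy index:
    between-group SD 0.054, between-participant SD 0.052, residual SD
    0.168.  Fixed effects: equal S1/S2 baselines with S3 lower by 0.06
    (the S2-S3 contrast scale), a -0.043 session step and a -0.009
    per-observation slope.
    """

    n_groups: int = 3
    n_participants_per_group: int = 4
    n_obs_per_cell: int = 12
    intercept: float = 0.30
    model_effects: dict = field(
        default_factory=lambda: {"S1": 0.0, "S2": 0.0, "S3": -0.06})
    session_effect: float = -0.043
    obs_slope: float = -0.009
    sd_group: float = 0.054
    sd_participant: float = 0.052
    sd_residual: float = 0.168
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_group, self.sd_participant, self.sd_residual) < 0:
            raise ValueError("variance components must be non-negative")
        if min(self.n_groups, self.n_participants_per_group,
               self.n_obs_per_cell) <= 0:
            raise ValueError("design sizes must be positive")


def gen_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-observation feature table from the hierarchical model.

    y = intercept + model_effect + session_effect*(session-1)
        + obs_slope*observation + b_group + b_participant + eps

    with Gaussian random intercepts and residuals at the configured SDs.
    Observations 1-6 fall in session 1, 7-12 in session 2 (split
    proportionally for other n_obs_per_cell).  Returns (table, truth)
    where truth carries the generating effects and the drawn intercepts.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    models = sorted(p.model_effects)
    b_group = rng.normal(0.0, p.sd_group, p.n_groups)
    b_part = rng.normal(
        0.0, p.sd_participant, (p.n_groups, p.n_participants_per_group))

    rows = []
    half = p.n_obs_per_cell / 2.0
    for g in range(p.n_groups):
        for j in range(p.n_participants_per_group):
            pid = f"G{g + 1}P{j + 1}"
            for m in models:
                for obs in range(1, p.n_obs_per_cell + 1):
                    session = 1 if obs <= half else 2
                    mu = (p.intercept + p.model_effects[m]
                          + p.session_effect * (session - 1)
                          + p.obs_slope * obs
                          + b_group[g] + b_part[g, j])
                    rows.append((f"{pid}-{m}-{obs:02d}", m, pid, f"G{g + 1}",
                                 session, obs,
                                 mu + rng.normal(0.0, p.sd_residual)))
    table = pd.DataFrame(rows, columns=[
        "segment_id", "sound_model", "participant_id", "group_id",
        "session", "observation_number", "value"])
    truth = {
        "params": asdict(p),
        "b_group": b_group,
        "b_participant": b_part,
    }
    return table, truth
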