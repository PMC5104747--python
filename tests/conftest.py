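"""Shared fixtures: analytic trajectories with closed-form kinematics."""

from __future__ import annotations

import numpy as np
import pytest

from moveson import MovementStyleParams, gen_trajectory
from moveson.trajectory_io import Trajectory


@pytest.fixture(scope="session")
def straight_traj() -> Trajectory:
    """10 s rectilinear monotone path at 0.5 m/s, 180 fps."""
    return gen_trajectory(MovementStyleParams(
        style="straight", mean_speed=0.5, duration=10.0, seed=0))


@pytest.fixture(scope="session")
def circle_traj() -> Trajectory:
    """Circle of radius 0.8 m at 1 m/s: |k| = 1.25 1/m, v = 1 m/s."""
    return gen_trajectory(MovementStyleParams(
        style="circle", mean_speed=1.0, radius=0.8, duration=10.0, seed=0))


def make_powerlaw_spiral(a: float = 0.2, b: float = 0.3, c: float = 0.25,
                         duration: float = 8.0, rate: float = 180.0
                         ) -> Trajectory:
    """Logarithmic-spiral arc traversed so that v = c * k**(-1/3) exactly.

    For r = a*exp(b*theta) the curvature k = 1 / (r*sqrt(1+b^2)) decreases
    strictly monotonically along arc length, so every short window sees
    nonzero variation of log k.  The two-thirds power law then fixes the
    angular rate dtheta/dt = A*exp(-2b*theta/3); it is integrated with RK4
    on the sampling grid.
    """
    n = int(duration * rate) + 1
    dt = 1.0 / rate
    theta = np.empty(n)
    theta[0] = 0.0
    A = c * (a * np.sqrt(1 + b * b)) ** (-2.0 / 3.0)
    f = lambda x: A * np.exp(-2.0 * b * x / 3.0)
    for i in range(1, n):
        k1 = f(theta[i - 1])
        k2 = f(theta[i - 1] + dt * k1 / 2)
        k3 = f(theta[i - 1] + dt * k2 / 2)
        k4 = f(theta[i - 1] + dt * k3)
        theta[i] = theta[i - 1] + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    r = a * np.exp(b * theta)
    t = np.arange(n) * dt
    return Trajectory(t=t, x=r * np.cos(theta), y=r * np.sin(theta), rate=rate)


@pytest.fixture(scope="session")
def spiral_traj() -> Trajectory:
    return make_powerlaw_spiral()
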