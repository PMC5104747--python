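"""Movement-quality indices from 2D trajectories.

Three indices summarize how a tracked head point moves:

* **Energy Index (EI)** — half the squared speed, the kinetic energy of a
  unit point mass: ``EI(f) = 1/2 * v(f)**2``.
* **Smoothness Index (SI)** — the Pearson correlation between log
  curvature and log speed over short (30 ms) windows.  Biological motion
  obeys a lawful curvature-velocity coupling (speed drops in bends,
  approximately ``v ∝ k**(-1/3)``), so smooth movement yields strongly
  negative correlations; jittery movement decouples the two and the
  correlation magnitude collapses.
* **Directness Index (DI)** — chord length between the trajectory's
  endpoints divided by its total path length; 1 for perfectly direct
  movement, near 0 for meandering or closed paths.

Derivatives are estimated by central finite differences after a
zero-phase moving-average smoothing (raw 180 fps differencing is
noise-dominated, especially for the second derivatives entering the
curvature).  The smoothing width, speed floor, window length and SI
variant are recorded in the metadata of every feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory

__all__ = [
    "FeatureConfig",
    "KinematicSeries",
    "FeatureRecord",
    "kinematics",
    "speed",
    "energy_index",
    "curvature",
    "smoothness_index",
    "directness_index",
    "summarize",
    "feature_table",
]

#: Speed floor (m/s) below which log-speed and the curvature denominator
#: are treated as undefined.
V_FLOOR = 1e-3


class NoMotionError(ValueError):
    """Raised when a trajectory contains no usable motion."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs for feature extraction (all recorded in metadata)."""

    smooth_frames: int = 5          # zero-phase moving-average width, samples
    v_floor: float = V_FLOOR        # m/s
    k_floor: float = 1e-6           # 1/m; smaller |k| is numerically straight
    si_window: float = 0.030        # seconds, non-overlapping windows
    si_variant: Literal["pearson", "simplified"] = "pearson"

    def metadata(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class KinematicSeries:
    """Per-sample kinematics on the differentiable interior of a trajectory."""

    t: np.ndarray
    v: np.ndarray          # speed, m/s, >= 0
    k: np.ndarray          # signed curvature, 1/m; NaN where v <= v_floor
    valid: np.ndarray      # mask: curvature defined (speed above floor)


@dataclass(frozen=True)
class FeatureRecord:
    """Per-observation feature summary plus design labels."""

    segment_id: str
    EI_mean: float
    SI_mean: float          # NaN when no window had enough valid samples
    DI: float
    sound_model: str = ""
    participant_id: str = ""
    group_id: str = ""
    session: int = 0
    observation_number: int = 0


def _moving_average(a: np.ndarray, width: int) -> np.ndarray:
    """Zero-phase moving average with edge-value padding (odd width)."""
    if width <= 1:
        return a
    if width % 2 == 0:
        width += 1
    half = width // 2
    padded = np.pad(a, half, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def _derivatives(traj: Trajectory, cfg: FeatureConfig):
    xs = _moving_average(traj.x, cfg.smooth_frames)
    ys = _moving_average(traj.y, cfg.smooth_frames)
    xd = np.gradient(xs, traj.t)
    yd = np.gradient(ys, traj.t)
    xdd = np.gradient(xd, traj.t)
    ydd = np.gradient(yd, traj.t)
    return xd, yd, xdd, ydd


def speed(traj: Trajectory, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Instantaneous speed ``v = sqrt(xdot**2 + ydot**2)``, m/s."""
    if len(traj) < 3:
        raise ValueError("speed needs at least 3 samples for central differences")
    xd, yd, _, _ = _derivatives(traj, cfg)
    return np.hypot(xd, yd)


def energy_index(traj: Trajectory, cfg: FeatureConfig = FeatureConfig(),
                 mass: float = 1.0) -> np.ndarray:
    """Kinetic-energy proxy per frame, ``EI = 1/2 * m * v**2`` (one point)."""
    v = speed(traj, cfg)
    return 0.5 * mass * v**2


def kinematics(traj: Trajectory, cfg: FeatureConfig = FeatureConfig()
               ) -> KinematicSeries:
    """Speed and signed curvature with a validity mask.

    Curvature ``k = (xdot*yddot - ydot*xddot) / (xdot**2 + ydot**2)**1.5``
    is left NaN wherever speed is at or below the configured floor (the
    denominator vanishes and log-speed is undefined there).
    """
    if len(traj) < 5:
        raise ValueError("curvature needs at least 5 samples")
    xd, yd, xdd, ydd = _derivatives(traj, cfg)
    v = np.hypot(xd, yd)
    valid = v > cfg.v_floor
    # boundary samples lack central-difference support (one-sided gradient
    # plus edge-padded smoothing); their second derivatives are biased
    edge = cfg.smooth_frames // 2 + 2
    valid[:edge] = False
    valid[-edge:] = False
    k = np.full_like(v, np.nan)
    num = xd * ydd - yd * xdd
    k[valid] = num[valid] / v[valid] ** 3
    return KinematicSeries(t=traj.t, v=v, k=k, valid=valid)


def curvature(traj: Trajectory, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Signed curvature series; raises if the trajectory never moves."""
    kin = kinematics(traj, cfg)
    if not kin.valid.any():
        raise NoMotionError("all samples below the speed floor")
    return kin.k


def _window_si(log_k: np.ndarray, log_v: np.ndarray, variant: str) -> float:
    if variant == "pearson":
        sk, sv = log_k.std(), log_v.std()
        if sk == 0.0 or sv == 0.0:
            return np.nan
        c = np.corrcoef(log_k, log_v)[0, 1]
        return float(c)
    # simplified variant: covariance approximated by 1, so SI reduces to
    # the reciprocal product of the log standard deviations.  Positive,
    # unbounded, and unit-dependent -- kept for fidelity, not as default.
    sk = log_k.std(ddof=1)
    sv = log_v.std(ddof=1)
    if sk == 0.0 or sv == 0.0:
        return np.nan
    return float(1.0 / (sk * sv))


def smoothness_index(traj: Trajectory, cfg: FeatureConfig = FeatureConfig()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window smoothness index.

    The trajectory is cut into non-overlapping windows of ``cfg.si_window``
    seconds.  Within each window the correlation of ``log |k|`` and
    ``log v`` is computed over valid samples (speed above floor, nonzero
    curvature).  Windows with fewer than 3 valid samples, or zero variance
    of either log series, yield NaN.

    Returns ``(t_centers, si)`` arrays, one entry per window.
    """
    kin = kinematics(traj, cfg)
    n_win = max(int(np.floor((kin.t[-1] - kin.t[0]) / cfg.si_window)), 1)
    edges = kin.t[0] + cfg.si_window * np.arange(n_win + 1)
    idx = np.searchsorted(kin.t, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    si = np.full(n_win, np.nan)
    for w in range(n_win):
        sl = slice(idx[w], idx[w + 1])
        k, v, ok = kin.k[sl], kin.v[sl], kin.valid[sl]
        ok = ok & np.isfinite(k) & (np.abs(k) > cfg.k_floor)
        if ok.sum() < 3:
            continue
        si[w] = _window_si(np.log(np.abs(k[ok])), np.log(v[ok]), cfg.si_variant)
    return centers, si


def directness_index(traj: Trajectory) -> float:
    """Chord length over path length, in (0, 1]; 1 iff perfectly direct."""
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    path = float(seg.sum())
    if path <= 0.0:
        raise NoMotionError("zero path length")
    chord = float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    return chord / path


def summarize(traj: Trajectory, manifest_row=None,
              cfg: FeatureConfig = FeatureConfig()) -> FeatureRecord:
    """Per-observation summary: mean EI over frames, mean SI over valid
    windows, DI over the whole excerpt, plus the design labels.

    EI is averaged over the interior frames with full central-difference
    support (the same samples the curvature mask admits), avoiding the
    boundary bias of one-sided derivative estimates."""
    edge = cfg.smooth_frames // 2 + 2
    ei = float(np.mean(energy_index(traj, cfg)[edge:-edge]))
    _, si = smoothness_index(traj, cfg)
    si_mean = float(np.nanmean(si)) if np.isfinite(si).any() else np.nan
    di = directness_index(traj)
    labels = {}
    if manifest_row is not None:
        get = lambda k, d: getattr(manifest_row, k, d)
        labels = dict(
            segment_id=str(get("segment_id", "")),
            sound_model=str(get("sound_model", "")),
            participant_id=str(get("participant_id", "")),
            group_id=str(get("group_id", "")),
            session=int(get("session", 0)),
            observation_number=int(get("observation_number", 0)),
        )
    return FeatureRecord(EI_mean=ei, SI_mean=si_mean, DI=di,
                         **({"segment_id": ""} | labels))


def feature_table(pairs, cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """FeatureRecords for (trajectory, manifest-row) pairs as a DataFrame."""
    recs = [summarize(t, row, cfg) for t, row in pairs]
    df = pd.DataFrame([asdict(r) for r in recs])
    df.attrs["feature_config"] = cfg.metadata()
    return df
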