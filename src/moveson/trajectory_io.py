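"""Reading, writing and basic repair of 2D marker trajectories.

A trajectory is a time-stamped sequence of planar head-marker positions,
in meters, in a room-centered coordinate frame.  Files are plain CSV with
a header row; the canonical columns are ``time_s, x_m, y_m`` (optionally
``marker_id``), or ``frame`` instead of ``time_s`` for frame-indexed
exports, converted to seconds via the nominal capture rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ObservationManifest",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
    "read_manifest",
    "detect_gaps",
    "fill_gaps",
]

DEFAULT_RATE = 180.0  # nominal optical-capture rate, frames per second


class TrajectoryFormatError(ValueError):
    """File does not expose the required columns."""


class TrajectoryValidationError(ValueError):
    """Data violates a trajectory invariant (monotone time, finiteness...)."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2D positions of one tracked marker.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, 0-based at segment
        start.
    x, y : ndarray
        Positions in meters, horizontal plane, origin at room center.
    rate : float
        Nominal sampling rate in Hz (informational; actual spacing is
        carried by ``t``).
    marker_id : str
        Opaque marker/rigid-body label.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float = DEFAULT_RATE
    marker_id: str = "marker"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or t.shape != x.shape or t.shape != y.shape:
            raise TrajectoryValidationError("t, x, y must be 1D arrays of equal length")
        if t.size < 2:
            raise TrajectoryValidationError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(t)):
            raise TrajectoryValidationError("non-finite timestamps")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrajectoryValidationError("non-finite positions")
        if np.any(np.diff(t) <= 0):
            raise TrajectoryValidationError("timestamps must be strictly increasing")
        if not self.rate > 0:
            raise TrajectoryValidationError("rate must be positive")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory with samples in the closed interval [t0, t1],
        re-zeroed so the first retained sample is at t=0."""
        m = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        if m.sum() < 2:
            raise TrajectoryValidationError("time slice keeps fewer than 2 samples")
        return replace(self, t=self.t[m] - self.t[m][0], x=self.x[m], y=self.y[m])


@dataclass(frozen=True)
class ObservationManifest:
    """Assignment of recording segments to design cells.

    Rows carry segment_id, sound_model (S1/S2/S3), participant_id,
    group_id, session (1 or 2), observation_number (1..12) and the
    segment's start/end time in the session recording, seconds.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "segment_id",
        "sound_model",
        "participant_id",
        "group_id",
        "session",
        "observation_number",
        "start_time",
        "end_time",
    )

    def __post_init__(self) -> None:
        df = self.table
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise TrajectoryFormatError(f"manifest missing columns: {sorted(missing)}")
        if df["segment_id"].duplicated().any():
            raise TrajectoryValidationError("segment_ids must be unique")
        if not (df["end_time"] > df["start_time"]).all():
            raise TrajectoryValidationError("end_time must exceed start_time")
        if not (df["observation_number"].astype(int) > 0).all():
            raise TrajectoryValidationError("observation_number must be positive")
        bad = set(df["sound_model"]) - {"S1", "S2", "S3"}
        if bad:
            raise TrajectoryValidationError(f"unknown sound models: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        return self.table.itertuples(index=False)


def read_trajectory(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    rate: float = DEFAULT_RATE,
) -> Trajectory:
    """Read a trajectory CSV.

    ``dialect`` maps canonical names (``time``, ``frame``, ``x``, ``y``,
    ``marker_id``) to the file's column names, for foreign exports.  A
    ``frame`` column is converted to seconds as ``frame / rate``.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    col = lambda key, default: dialect.get(key, default)

    tcol, fcol = col("time", "time_s"), col("frame", "frame")
    xcol, ycol = col("x", "x_m"), col("y", "y_m")
    for c in (xcol, ycol):
        if c not in df.columns:
            raise TrajectoryFormatError(f"missing column {c!r} in {path}")
    if tcol in df.columns:
        t = df[tcol].to_numpy(dtype=float)
    elif fcol in df.columns:
        t = df[fcol].to_numpy(dtype=float) / rate
    else:
        raise TrajectoryFormatError(f"need a {tcol!r} or {fcol!r} column in {path}")

    mcol = col("marker_id", "marker_id")
    marker = str(df[mcol].iloc[0]) if mcol in df.columns else "marker"
    return Trajectory(t=t, x=df[xcol].to_numpy(float), y=df[ycol].to_numpy(float),
                      rate=rate, marker_id=marker)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the canonical CSV (full float precision; round-trips to 1e-9)."""
    if str(path) == "":
        raise ValueError("empty output path")
    df = pd.DataFrame(
        {"time_s": traj.t, "x_m": traj.x, "y_m": traj.y,
         "marker_id": traj.marker_id}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_manifest(path: str | Path) -> ObservationManifest:
    return ObservationManifest(pd.read_csv(path))


def detect_gaps(traj: Trajectory, max_dt: float) -> list[tuple[float, float]]:
    """Intervals between consecutive samples whose spacing exceeds max_dt."""
    if not max_dt > 0:
        raise ValueError("max_dt must be positive")
    dt = np.diff(traj.t)
    idx = np.nonzero(dt > max_dt)[0]
    return [(float(traj.t[i]), float(traj.t[i + 1])) for i in idx]


def fill_gaps(traj: Trajectory, max_fill: float, nominal_dt: float | None = None
              ) -> Trajectory:
    """Linearly interpolate short gaps onto the nominal grid.

    Gaps no longer than ``max_fill`` seconds are filled with samples on the
    nominal grid (spacing ``1/rate`` unless ``nominal_dt`` is given);
    longer gaps are left intact.  Existing samples are never altered.
    """
    if max_fill < 0:
        raise ValueError("max_fill must be >= 0")
    dt_nom = nominal_dt if nominal_dt is not None else 1.0 / traj.rate
    t_out = [traj.t[:1]]
    x_out = [traj.x[:1]]
    y_out = [traj.y[:1]]
    for i in range(1, len(traj)):
        gap = traj.t[i] - traj.t[i - 1]
        if dt_nom * 1.5 < gap <= max_fill:
            n_new = int(round(gap / dt_nom)) - 1
            if n_new > 0:
                tt = traj.t[i - 1] + dt_nom * np.arange(1, n_new + 1)
                tt = tt[tt < traj.t[i] - 1e-12]
                frac = (tt - traj.t[i - 1]) / gap
                x_out.append(traj.x[i - 1] + frac * (traj.x[i] - traj.x[i - 1]))
                y_out.append(traj.y[i - 1] + frac * (traj.y[i] - traj.y[i - 1]))
                t_out.append(tt)
        t_out.append(traj.t[i : i + 1])
        x_out.append(traj.x[i : i + 1])
        y_out.append(traj.y[i : i + 1])
    return replace(traj, t=np.concatenate(t_out), x=np.concatenate(x_out),
                   y=np.concatenate(y_out))
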