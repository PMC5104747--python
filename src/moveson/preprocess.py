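"""Segmentation, exclusion rules and normalization for observation data.

Recordings are cut into per-observation excerpts, trimmed to the stable
middle part, screened for tracking defects (marker crossover, occlusion
gaps, wandering out of the tracked area), and the resulting per-observation
feature table is min-max normalized to [0, 1] per feature over the whole
retained dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory, TrajectoryValidationError, detect_gaps

__all__ = [
    "QualityRules",
    "QualityReport",
    "trim_observation",
    "flag_crossover",
    "apply_exclusions",
    "normalize_unit_range",
]

#: Tracked floor area, meters (width along x, height along y), centered at 0.
AREA_WIDTH = 4.66
AREA_HEIGHT = 5.40

#: Observation timing: raw segments are 36 s + 1 s fade; trimming the first
#: and last 6 s leaves a 25 s excerpt.
DEFAULT_LEAD = 6.0
DEFAULT_TAIL = 6.0


@dataclass(frozen=True)
class QualityRules:
    """Thresholds for automatic observation exclusion.

    v_max : maximum plausible inter-sample speed, m/s.  Displacements
        implying faster motion are read as marker crossover (label swaps
        between nearby markers produce near-instantaneous jumps); 10 m/s
        is far above child locomotion and far below swap speeds.
    min_samples : minimum retained sample count; default half of the
        nominal 25 s excerpt at the capture rate.
    max_out_of_area_fraction : tolerated fraction of samples outside the
        tracked area.
    max_gap : occlusion gap length, seconds, above which tracking is
        considered insufficient.
    """

    v_max: float = 10.0
    min_samples: int | None = None
    max_out_of_area_fraction: float = 0.2
    max_gap: float = 1.0
    area_width: float = AREA_WIDTH
    area_height: float = AREA_HEIGHT

    def resolved_min_samples(self, rate: float, duration: float = 25.0) -> int:
        if self.min_samples is not None:
            return self.min_samples
        return int(0.5 * duration * rate)


@dataclass(frozen=True)
class QualityReport:
    segment_id: str
    n_samples: int
    crossover_flag: bool
    out_of_area_fraction: float
    longest_gap: float
    excluded: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded observations must carry a reason")
        if not 0.0 <= self.out_of_area_fraction <= 1.0:
            raise ValueError("out_of_area_fraction must lie in [0, 1]")


def trim_observation(traj: Trajectory, lead: float = DEFAULT_LEAD,
                     tail: float = DEFAULT_TAIL) -> Trajectory:
    """Drop the first ``lead`` and last ``tail`` seconds of an observation.

    Removes the cross-fade between sound models and the settling-in period;
    a 36 s + 1 s fade segment with defaults yields the 25 s analysis excerpt.
    """
    if lead < 0 or tail < 0:
        raise ValueError("lead and tail must be non-negative")
    if traj.duration <= lead + tail:
        raise TrajectoryValidationError(
            f"segment of {traj.duration:.3f}s too short to trim {lead}+{tail}s"
        )
    return traj.slice_time(traj.t[0] + lead, traj.t[-1] - tail)


def flag_crossover(traj: Trajectory, v_max: float = 10.0) -> bool:
    """True iff any consecutive-sample displacement implies speed > v_max.

    Marker label swaps teleport the track across the room within one frame,
    which no real head movement can do.
    """
    if not v_max > 0:
        raise ValueError("v_max must be positive")
    if not np.isfinite(v_max):
        return False
    dt = np.diff(traj.t)
    step = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return bool(np.any(step / dt > v_max))


def _out_of_area_fraction(traj: Trajectory, width: float, height: float) -> float:
    out = (np.abs(traj.x) > width / 2) | (np.abs(traj.y) > height / 2)
    return float(np.mean(out))


def apply_exclusions(
    segments: list[tuple[Trajectory, object]],
    rules: QualityRules = QualityRules(),
) -> tuple[list[tuple[Trajectory, object]], list[QualityReport]]:
    """Screen (trajectory, manifest-row) pairs against the quality rules.

    Returns the kept pairs and one QualityReport per input segment, in
    order.  Exclusion reasons, checked in order: ``crossover``,
    ``occlusion_gap``, ``too_few_samples``, ``out_of_area``.
    """
    kept: list[tuple[Trajectory, object]] = []
    reports: list[QualityReport] = []
    for traj, row in segments:
        seg_id = str(getattr(row, "segment_id", ""))
        cross = flag_crossover(traj, rules.v_max)
        gaps = detect_gaps(traj, max_dt=3.0 / traj.rate)
        longest = max((b - a for a, b in gaps), default=0.0)
        oof = _out_of_area_fraction(traj, rules.area_width, rules.area_height)
        n = len(traj)
        min_n = rules.resolved_min_samples(traj.rate, max(traj.duration, 1e-9))

        reason = ""
        if cross:
            reason = "crossover"
        elif longest > rules.max_gap:
            reason = "occlusion_gap"
        elif n < min_n:
            reason = "too_few_samples"
        elif oof > rules.max_out_of_area_fraction:
            reason = "out_of_area"

        reports.append(QualityReport(
            segment_id=seg_id, n_samples=n, crossover_flag=cross,
            out_of_area_fraction=oof, longest_gap=longest,
            excluded=bool(reason), reason=reason,
        ))
        if not reason:
            kept.append((traj, row))
    return kept, reports


def normalize_unit_range(values) -> np.ndarray:
    """Affine min-max rescaling to [0, 1].

    Applied per feature over the whole retained dataset (pooled across
    participants), so between-participant contrasts survive rescaling.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
        raise ValueError("normalization needs at least two distinct finite values")
    return (v - lo) / (hi - lo)


def normalize_features(table: pd.DataFrame,
                       columns=("EI_mean", "SI_mean", "DI")) -> pd.DataFrame:
    """Return a copy of the feature table with ``columns`` min-max scaled."""
    out = table.copy()
    for c in columns:
        if c in out.columns:
            out[c] = normalize_unit_range(out[c].to_numpy())
    return out
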