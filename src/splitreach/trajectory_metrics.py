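"""Kinematic measure extraction from raw reach trajectories.

A reach trial decomposes into initiation time (IT: stimulus onset to movement
onset), movement time (MT: movement onset to response completion) and response
time (RT = IT + MT). Curvature (CURV) quantifies in-flight corrections: the
maximum deviation of the observed path from the direct path between movement
onset and the selected target, divided by the direct path length. Partial
errors — reaches that start toward the wrong target and are corrected online —
show up as large CURV even when the final response is correct.

For release-and-press interfaces (keyboard, touchscreen) no trajectory exists:
IT and MT come from key-release and key-press timestamps and CURV is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError, NoMovementError

__all__ = [
    "Trajectory",
    "MeasureSet",
    "detect_movement_onset",
    "compute_curvature",
    "extract_measures",
    "measures_from_timestamps",
    "extract_measures_batch",
]

#: Default movement-onset criterion: Euclidean displacement from the start
#: point, in millimetres.
DEFAULT_ONSET_THRESHOLD_MM = 5.0


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped position samples for one trial's reach.

    ``t`` is in milliseconds and strictly increasing; ``xy`` holds one row per
    sample with 2 or 3 spatial columns (mm; z defaults to absent). The last
    sample must coincide with ``end_point`` (the selected target contact).
    """

    trial_uid: str
    t: np.ndarray
    xy: np.ndarray
    start_point: np.ndarray
    end_point: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "start_point", np.asarray(self.start_point, dtype=float))
        object.__setattr__(self, "end_point", np.asarray(self.end_point, dtype=float))
        if t.ndim != 1 or len(t) != len(xy):
            raise ValueError(f"{self.trial_uid}: t and xy lengths differ")
        if len(t) < 3:
            raise ValueError(f"{self.trial_uid}: need >= 3 samples, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.trial_uid}: sample times must be strictly increasing")
        if xy.shape[1] not in (2, 3):
            raise ValueError(f"{self.trial_uid}: positions must be 2-D or 3-D")
        if not np.allclose(xy[-1], self.end_point):
            raise ValueError(f"{self.trial_uid}: last sample must equal end_point")

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class MeasureSet:
    """Per-trial kinematic measures (ms; ``curv`` unitless, None when no
    trajectory was recorded)."""

    it: float
    mt: float
    rt: float
    curv: float | None = None

    def __post_init__(self):
        if self.it < 0 or self.mt < 0 or self.rt < 0:
            raise ValueError("measures must be nonnegative")


def detect_movement_onset(
    trajectory: Trajectory,
    stimulus_onset: float = 0.0,
    displacement_threshold: float = DEFAULT_ONSET_THRESHOLD_MM,
) -> float:
    """Time (ms) of the first sample displaced from the start point by more
    than ``displacement_threshold`` mm, at or after stimulus onset.

    Raises :class:`NoMovementError` if no sample ever exceeds the threshold.
    """
    if displacement_threshold <= 0:
        raise ValueError("displacement_threshold must be > 0")
    start = trajectory.start_point
    disp = np.linalg.norm(trajectory.xy - start, axis=1)
    eligible = (trajectory.t >= stimulus_onset) & (disp > displacement_threshold)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise NoMovementError(
            f"{trajectory.trial_uid}: no sample displaced > "
            f"{displacement_threshold} mm from start"
        )
    return float(trajectory.t[idx[0]])


def compute_curvature(trajectory: Trajectory, onset_time: float) -> float:
    """Maximum deviation of the post-onset path from the direct path, as a
    fraction of the direct path length.

    The direct path runs from the position at movement onset to the trial's
    end point; deviation is the perpendicular distance of each post-onset
    sample to the infinite line through those two points (not to the segment).
    A perfectly straight reach yields 0.
    """
    if onset_time >= trajectory.t[-1]:
        raise GeometryError(
            f"{trajectory.trial_uid}: onset at or after the final sample"
        )
    post = trajectory.t >= onset_time
    pts = trajectory.xy[post]
    onset_pos = pts[0]
    direct = trajectory.end_point - onset_pos
    length = float(np.linalg.norm(direct))
    if length == 0.0:
        raise GeometryError(f"{trajectory.trial_uid}: zero-length direct path")
    rel = pts - onset_pos
    # Perpendicular distance to the infinite line: ||rel - (rel.u)u||.
    u = direct / length
    along = rel @ u
    perp = rel - np.outer(along, u)
    max_dev = float(np.linalg.norm(perp, axis=1).max())
    return max_dev / length


def extract_measures(
    trajectory: Trajectory,
    stimulus_onset: float,
    response_completion_time: float,
    displacement_threshold: float = DEFAULT_ONSET_THRESHOLD_MM,
) -> MeasureSet:
    """IT/MT/RT/CURV for one trajectory trial.

    IT = onset - stimulus onset; MT = response completion - onset;
    RT = response completion - stimulus onset; CURV from
    :func:`compute_curvature` at the detected onset.
    """
    if response_completion_time <= stimulus_onset:
        raise ValueError("response_completion_time must exceed stimulus_onset")
    onset = detect_movement_onset(trajectory, stimulus_onset, displacement_threshold)
    curv = compute_curvature(trajectory, onset)
    return MeasureSet(
        it=onset - stimulus_onset,
        mt=response_completion_time - onset,
        rt=response_completion_time - stimulus_onset,
        curv=curv,
    )


def measures_from_timestamps(
    stimulus_onset: float, release_time: float, press_time: float
) -> MeasureSet:
    """Release-and-press variant: IT/MT from key-release and key-press
    timestamps; CURV is absent because no path was recorded."""
    if not stimulus_onset <= release_time <= press_time:
        raise ValueError("expected stimulus_onset <= release_time <= press_time")
    return MeasureSet(
        it=release_time - stimulus_onset,
        mt=press_time - release_time,
        rt=press_time - stimulus_onset,
        curv=None,
    )


def extract_measures_batch(
    trajectories: Mapping[str, Trajectory] | Iterable[Trajectory],
    completion_times: Mapping[str, float] | None = None,
    stimulus_onset: float = 0.0,
    displacement_threshold: float = DEFAULT_ONSET_THRESHOLD_MM,
) -> pd.DataFrame:
    """Extract measures for a trajectory store.

    Returns one row per trial (``trial_uid, it_ms, mt_ms, rt_ms, curv``);
    trials where onset detection fails are returned with NaN measures and
    ``flag='no_movement'`` so downstream filtering can drop them rather than
    aborting the batch. ``completion_times`` defaults to each trajectory's
    final sample time.
    """
    if isinstance(trajectories, Mapping):
        items = list(trajectories.values())
    else:
        items = list(trajectories)
    rows = []
    for traj in items:
        completion = (
            completion_times[traj.trial_uid]
            if completion_times is not None
            else float(traj.t[-1])
        )
        try:
            ms = extract_measures(traj, stimulus_onset, completion, displacement_threshold)
            rows.append(
                {"trial_uid": traj.trial_uid, "it_ms": ms.it, "mt_ms": ms.mt,
                 "rt_ms": ms.rt, "curv": ms.curv, "flag": ""}
            )
        except (NoMovementError, GeometryError) as err:
            rows.append(
                {"trial_uid": traj.trial_uid, "it_ms": np.nan, "mt_ms": np.nan,
                 "rt_ms": np.nan, "curv": np.nan, "flag": type(err).__name__}
            )
    return pd.DataFrame(rows)
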