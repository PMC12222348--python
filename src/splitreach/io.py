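"""CSV readers/writers for trial tables and trajectory stores.

Long format throughout: one row per trial in the trial table, one row per
sample in the trajectory table. Times are milliseconds, positions
millimetres, curvature unitless; RFC-4180 CSV with header rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .trajectory_metrics import Trajectory

__all__ = [
    "REQUIRED_TRIAL_COLUMNS",
    "OPTIONAL_TRIAL_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "read_trajectories",
    "write_trajectories",
]

REQUIRED_TRIAL_COLUMNS = (
    "participant_id", "block", "trial_index", "congruency",
    "target_side", "response_side", "accuracy", "rt_ms",
)
OPTIONAL_TRIAL_COLUMNS = (
    "it_ms", "mt_ms", "curv", "age_group", "condition_id",
    "partial_error", "commitment_fraction",
)
_TIMING_COLUMNS = ("rt_ms", "it_ms", "mt_ms", "curv")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Checks required columns, duplicate (participant, block, trial_index)
    keys, numeric timing columns, and coerces congruency/side codes to their
    canonical single-letter uppercase forms. Raises :class:`SchemaError`
    naming the column and offending row numbers (1-based data rows).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    dup = df.duplicated(subset=["participant_id", "block", "trial_index"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:10]
        raise SchemaError(f"{path}: duplicate trial keys at data row(s) {rows}")

    for col in _TIMING_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 1).tolist()[:10]
            raise SchemaError(f"{path}: non-numeric {col} at data row(s) {rows}")
        df[col] = coerced

    df["congruency"] = df["congruency"].astype(str).str.strip().str.upper().str[0]
    bad = ~df["congruency"].isin(["C", "I"])
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(f"{path}: congruency not C/I at data row(s) {rows}")
    for col in ("target_side", "response_side"):
        df[col] = df[col].astype(str).str.strip().str.upper().str[0]
    df["accuracy"] = df["accuracy"].astype(str).str.strip().str.lower()
    df.attrs["missing_optional_columns"] = [
        c for c in OPTIONAL_TRIAL_COLUMNS if c not in df.columns
    ]
    return df


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)


def write_trajectories(trajectories: Mapping[str, Trajectory], path: str | Path) -> None:
    """Write a trajectory store as long CSV (trial_uid, t_ms, x_mm, y_mm[, z_mm])."""
    frames = []
    for uid, traj in trajectories.items():
        d = {"trial_uid": uid, "t_ms": traj.t,
             "x_mm": traj.xy[:, 0], "y_mm": traj.xy[:, 1]}
        if traj.xy.shape[1] == 3:
            d["z_mm"] = traj.xy[:, 2]
        frames.append(pd.DataFrame(d))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> dict[str, Trajectory]:
    """Read a long trajectory CSV back into a trial_uid -> Trajectory store.

    Start point is the first sample, end point the last (target contact).
    """
    df = pd.read_csv(path)
    needed = {"trial_uid", "t_ms", "x_mm", "y_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing trajectory column(s) {sorted(missing)}")
    cols = ["x_mm", "y_mm"] + (["z_mm"] if "z_mm" in df.columns else [])
    out = {}
    for uid, grp in df.groupby("trial_uid", sort=False):
        grp = grp.sort_values("t_ms")
        xy = grp[cols].to_numpy(dtype=float)
        out[str(uid)] = Trajectory(
            trial_uid=str(uid), t=grp["t_ms"].to_numpy(dtype=float), xy=xy,
            start_point=xy[0], end_point=xy[-1],
        )
    return out
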