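"""Per-participant condition means, congruency-effect difference scores,
descriptive statistics, and component correlations.

The congruency effect for a measure is the participant's incongruent-trial
mean minus their congruent-trial mean. For ``error_rate`` the cell statistic
is the proportion of overt errors, computed on a table that has *not* been
accuracy-filtered (pass the bounds-filtered, accuracy-unfiltered table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "MEASURE_COLUMNS",
    "DescriptiveStats",
    "participant_condition_means",
    "describe_effects",
    "component_correlation",
]

#: Maps measure names to trial-table columns; ``error_rate`` is derived from
#: the ``accuracy`` column.
MEASURE_COLUMNS = {
    "rt": "rt_ms",
    "it": "it_ms",
    "mt": "mt_ms",
    "curv": "curv",
    "error_rate": "accuracy",
}


@dataclass(frozen=True)
class DescriptiveStats:
    """Sample descriptives of an effect vector.

    ``skew`` is the adjusted Fisher-Pearson coefficient and ``kurtosis`` the
    sample *excess* kurtosis (normal -> 0), both with small-sample bias
    correction; they are NaN (and ``degenerate`` True) for constant vectors.
    """

    m: float
    sd: float
    min: float
    max: float
    skew: float
    kurtosis: float
    n: int
    degenerate: bool = False


def participant_condition_means(trials: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-participant congruent/incongruent means and the difference score.

    Returns columns ``participant_id, measure, mean_congruent,
    mean_incongruent, effect, n_congruent, n_incongruent, flagged``.
    ``flagged`` marks participants with an empty cell (their means/effect are
    NaN). For timing/curvature measures pass the filtered table; for
    ``error_rate`` pass the table before error/post-error exclusion.
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(MEASURE_COLUMNS)}")
    col = MEASURE_COLUMNS[measure]
    if col not in trials.columns:
        raise ValueError(f"measure {measure!r} needs column {col!r}, absent from table")
    df = trials[["participant_id", "congruency", col]].copy()
    if measure == "error_rate":
        df["_value"] = (df[col].astype(str) == "error").astype(float)
    else:
        df["_value"] = df[col].astype(float)
    df = df.dropna(subset=["_value"])

    grouped = df.groupby(["participant_id", "congruency"])["_value"].agg(["mean", "size"])
    wide_mean = grouped["mean"].unstack()
    wide_n = grouped["size"].unstack().fillna(0).astype(int)
    for cell in ("C", "I"):
        if cell not in wide_mean.columns:
            wide_mean[cell] = np.nan
            wide_n[cell] = 0

    out = pd.DataFrame({
        "participant_id": wide_mean.index,
        "measure": measure,
        "mean_congruent": wide_mean["C"].to_numpy(),
        "mean_incongruent": wide_mean["I"].to_numpy(),
        "effect": (wide_mean["I"] - wide_mean["C"]).to_numpy(),
        "n_congruent": wide_n["C"].to_numpy(),
        "n_incongruent": wide_n["I"].to_numpy(),
    }).reset_index(drop=True)
    out["flagged"] = (out["n_congruent"] < 1) | (out["n_incongruent"] < 1)
    return out


def describe_effects(effects: np.ndarray | pd.Series) -> DescriptiveStats:
    """M, SD, Min, Max, Skew and excess Kurtosis of an effect vector.

    Requires n >= 4 (sample excess kurtosis is undefined below that). SD uses
    n-1; skew/kurtosis use the bias-corrected estimators common in stats
    packages. A constant vector gets NaN shape statistics and is flagged
    ``degenerate``.
    """
    x = np.asarray(effects, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 observations for descriptives, got {n}")
    sd = float(np.std(x, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return DescriptiveStats(
        m=float(np.mean(x)), sd=sd, min=float(np.min(x)), max=float(np.max(x)),
        skew=skew, kurtosis=kurt, n=n, degenerate=degenerate,
    )


def component_correlation(effect_table: pd.DataFrame) -> float:
    """Pearson correlation across participants between the congruent-mean and
    incongruent-mean component scores.

    High component correlations are exactly the condition under which
    difference scores lose reliability even when both components are
    individually reliable. Returns NaN when a component has zero variance
    (undefined correlation) — callers treat NaN as a flag.
    """
    sub = effect_table.loc[~effect_table["flagged"]]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 participants with both cells, got {len(sub)}"
        )
    x = sub["mean_congruent"].to_numpy(dtype=float)
    y = sub["mean_incongruent"].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
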