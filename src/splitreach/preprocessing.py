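"""Trial-sequence condition coding, the exclusion ladder, and log transform.

The three stages are scikit-learn transformers operating on long-format trial
tables (one row per trial), so they compose in an ``sklearn.pipeline.Pipeline``:

* :class:`ConditionCoder` derives previous-trial congruency, response
  repetition, post-error and first-of-block flags from trial order.
* :class:`TrialFilter` applies the exclusion ladder in a fixed order —
  first-of-block, overt errors, post-error trials, absolute RT bounds by age
  group, then a per-participant per-congruency SD rule recomputed on the
  survivors — attributing each removed trial to the first rule that caught it.
* :class:`LogTransformer` replaces selected measure columns with their natural
  log (positive-skewed response times are routinely analyzed on the log scale;
  congruency effects then become differences of log-means).

The module-level functions :func:`code_conditions`, :func:`filter_trials` and
:func:`log_transform` are thin wrappers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import FilterConfig
from .errors import DataIntegrityError, TransformError

__all__ = [
    "ConditionCoder",
    "TrialFilter",
    "LogTransformer",
    "code_conditions",
    "filter_trials",
    "log_transform",
    "EXCLUSION_RULES",
]

#: Ladder order; the exclusion log attributes each trial to the first match.
EXCLUSION_RULES = ("first_of_block", "error", "post_error", "rt_bounds", "rt_sd")

_KEY = ["participant_id", "block", "trial_index"]


def _check_ordering(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise DataIntegrityError(f"duplicate (participant, block, trial_index) at rows {rows}")
    for (pid, blk), grp in df.groupby(["participant_id", "block"], sort=False):
        idx = grp["trial_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise DataIntegrityError(
                f"trial_index not strictly increasing for participant {pid} block {blk}"
            )


class ConditionCoder(BaseEstimator, TransformerMixin):
    """Derive sequence condition codes from trial order.

    Adds ``prev_congruency`` ('c'/'i'/'none'), ``response_repetition``
    ('repetition'/'alternation'/'none'), ``post_error`` and ``first_of_block``.
    Previous-trial codes come strictly from the immediately preceding trial
    within the same block; the first trial of each block has no codes.
    """

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.sort_values(_KEY, kind="stable").reset_index(drop=True)
        _check_ordering(df)

        same_block = (
            (df["participant_id"] == df["participant_id"].shift())
            & (df["block"] == df["block"].shift())
        ).to_numpy()
        first = ~same_block

        prev_cong = df["congruency"].shift().to_numpy(dtype=object)
        prev_resp = df["response_side"].shift().to_numpy(dtype=object)
        prev_acc = df["accuracy"].shift().to_numpy(dtype=object)

        df["first_of_block"] = first
        df["prev_congruency"] = np.where(
            first, "none", np.where(prev_cong == "I", "i", "c")
        )
        df["response_repetition"] = np.where(
            first,
            "none",
            np.where(df["response_side"].to_numpy(dtype=object) == prev_resp,
                     "repetition", "alternation"),
        )
        df["post_error"] = np.where(first, False, prev_acc == "error").astype(bool)
        return df


class TrialFilter(BaseEstimator, TransformerMixin):
    """Apply the exclusion ladder; ``transform`` returns the retained trials.

    Fitted attributes (set by ``transform``):

    exclusion_log_ : DataFrame (participant_id, rule, n_removed)
        One row per participant x rule, additive: the per-participant sums
        plus the retained counts equal the input counts.
    low_trial_participants_ : list of participant ids
        Participants left with < 2 retained trials in either congruency cell;
        retained in the output but flagged for the reliability stage.
    """

    def __init__(self, config: FilterConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config or FilterConfig()
        cfg.validate()
        required = {"prev_congruency", "post_error", "first_of_block"}
        if not required <= set(X.columns):
            raise DataIntegrityError(
                "conditions must be coded before filtering (run ConditionCoder)"
            )
        df = X.reset_index(drop=True)
        rule = pd.Series("", index=df.index, dtype=object)

        def mark(mask: pd.Series | np.ndarray, name: str) -> None:
            mask = np.asarray(mask, dtype=bool) & (rule == "").to_numpy()
            rule.iloc[np.flatnonzero(mask)] = name

        if cfg.exclude_first_of_block:
            mark(df["first_of_block"], "first_of_block")
        if cfg.exclude_errors:
            mark(df["accuracy"].to_numpy(dtype=object) == "error", "error")
        if cfg.exclude_post_error:
            mark(df["post_error"], "post_error")

        age = (
            df["age_group"].astype(str)
            if "age_group" in df.columns
            else pd.Series("adult", index=df.index)
        )
        rt_max = np.where(age.to_numpy() == "child", cfg.rt_max_child, cfg.rt_max_adult)
        rt = df["rt_ms"].to_numpy(dtype=float)
        mark((rt < cfg.rt_min) | (rt > rt_max), "rt_bounds")

        # SD rule: per participant x congruency stats on survivors of stages 1-4
        survivor = (rule == "").to_numpy()
        sub = df.loc[survivor]
        stats = (
            sub.groupby(["participant_id", "congruency"], sort=False)["rt_ms"]
            .agg(["mean", "std"])
            .rename(columns={"mean": "_m", "std": "_s"})
        )
        joined = df.join(stats, on=["participant_id", "congruency"])
        sd = joined["_s"].fillna(0.0).to_numpy()
        center = joined["_m"].to_numpy()
        out_of_band = np.abs(rt - center) > cfg.sd_cutoff * sd
        mark(survivor & out_of_band, "rt_sd")

        retained = df.loc[(rule == "").to_numpy()].reset_index(drop=True)

        removed = df.loc[(rule != "").to_numpy()].assign(rule=rule[rule != ""])
        log = (
            removed.groupby(["participant_id", "rule"], sort=True)
            .size()
            .rename("n_removed")
            .reset_index()
        )
        self.exclusion_log_ = log
        counts = (
            retained.groupby(["participant_id", "congruency"]).size().unstack(fill_value=0)
        )
        low = []
        for pid in df["participant_id"].unique():
            row = counts.loc[pid] if pid in counts.index else None
            n_c = int(row.get("C", 0)) if row is not None else 0
            n_i = int(row.get("I", 0)) if row is not None else 0
            if n_c < 2 or n_i < 2:
                low.append(pid)
        self.low_trial_participants_ = low
        return retained


class LogTransformer(BaseEstimator, TransformerMixin):
    """Natural-log transform of selected measure columns (default rt/it/mt)."""

    def __init__(self, measures: Sequence[str] = ("rt_ms", "it_ms", "mt_ms")):
        self.measures = measures

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        for col in self.measures:
            if col not in df.columns:
                raise TransformError(f"column {col!r} not present")
            vals = df[col].to_numpy(dtype=float)
            bad = ~(vals > 0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise TransformError(
                    f"log transform of {col!r}: nonpositive value {vals[i]} at row {i} "
                    f"(participant {df['participant_id'].iloc[i]})"
                )
            df[col] = np.log(vals)
        return df


def code_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :class:`ConditionCoder`."""
    return ConditionCoder().fit_transform(trials)


def filter_trials(
    trials: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion ladder; returns (retained table, exclusion log)."""
    f = TrialFilter(config)
    retained = f.fit_transform(trials)
    return retained, f.exclusion_log_


def log_transform(
    trials: pd.DataFrame, measures: Sequence[str] = ("rt_ms", "it_ms", "mt_ms")
) -> pd.DataFrame:
    """Functional wrapper over :class:`LogTransformer`."""
    return LogTransformer(measures).fit_transform(trials)
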