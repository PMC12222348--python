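"""Sequence-effect decomposition: 2 x 2 x 2 within-subject ANOVA.

Cells cross current-trial congruency (C/I), previous-trial congruency (c/i)
and response-repetition type (alternation/repetition). With all factors at
two levels every effect — three mains, three two-way interactions and the
three-way interaction — is a single-degree-of-freedom contrast over the eight
unweighted cell means, so F(1, N-1) equals the squared one-sample t of the
per-participant contrast scores. This is exact, not an approximation, and is
cross-validated against a general repeated-measures ANOVA routine in the
tests.

The scientifically interesting pattern in reaching tasks: initiation time
shows main effects of current and previous congruency (threshold adjustment),
while movement time shows a three-way interaction driven by particularly slow
movements on incongruent trials that follow a congruent trial and repeat the
previous response (cI-r trials) — the signature of in-flight conflict
resolution.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .effects import MEASURE_COLUMNS
from .errors import InsufficientDataError

__all__ = ["CELLS", "EFFECTS", "cell_means", "rm_anova_2x2x2", "SequenceAnova"]

#: The 8 design cells as (congruency, prev_congruency, repetition) codes,
#: e.g. ("I", "c", "repetition") is a cI-r trial.
CELLS = tuple(itertools.product(("C", "I"), ("c", "i"),
                                ("alternation", "repetition")))

#: Effect names in reporting order.
EFFECTS = (
    "congruency",
    "prev_congruency",
    "repetition",
    "congruency:prev_congruency",
    "congruency:repetition",
    "prev_congruency:repetition",
    "congruency:prev_congruency:repetition",
)


def _cell_label(cell: tuple[str, str, str]) -> str:
    cong, prev, rep = cell
    return f"{prev}{cong}-{'r' if rep == 'repetition' else 'a'}"


def _contrast_weights(effect: str) -> np.ndarray:
    """+-1 weights over the 8 cells for a main effect or interaction.

    Main-effect sign is +1 for the I / i / repetition level; interaction
    weights are products of the involved mains.
    """
    signs = {
        "congruency": {"C": -1.0, "I": +1.0},
        "prev_congruency": {"c": -1.0, "i": +1.0},
        "repetition": {"alternation": -1.0, "repetition": +1.0},
    }
    factors = effect.split(":")
    w = np.ones(len(CELLS))
    for j, (cong, prev, rep) in enumerate(CELLS):
        levels = {"congruency": cong, "prev_congruency": prev, "repetition": rep}
        for f in factors:
            w[j] *= signs[f][levels[f]]
    return w


def cell_means(trials: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Unweighted per-participant means for the 8 sequence cells.

    Input must be condition-coded and should exclude first-of-block trials
    (they carry no previous-trial codes; any remaining are dropped here).
    Returns one row per participant with a column per cell (labels like
    ``cI-r``), matching ``n_*`` count columns, and ``complete`` marking
    participants with all 8 cells populated. Incomplete participants are
    excluded listwise by :func:`rm_anova_2x2x2`.
    """
    col = MEASURE_COLUMNS[measure]
    needed = {"prev_congruency", "response_repetition", col}
    if not needed <= set(trials.columns):
        raise ValueError(f"table missing columns {sorted(needed - set(trials.columns))}")
    df = trials.loc[
        trials["prev_congruency"].isin(["c", "i"])
        & trials["response_repetition"].isin(["alternation", "repetition"])
    ]
    grouped = (
        df.groupby(["participant_id", "congruency", "prev_congruency",
                    "response_repetition"])[col]
        .agg(["mean", "size"])
    )
    rows = []
    for pid in df["participant_id"].unique():
        row: dict = {"participant_id": pid}
        complete = True
        for cell in CELLS:
            key = (pid, *cell)
            label = _cell_label(cell)
            if key in grouped.index:
                row[label] = float(grouped.loc[key, "mean"])
                row[f"n_{label}"] = int(grouped.loc[key, "size"])
            else:
                row[label] = np.nan
                row[f"n_{label}"] = 0
                complete = False
        row["complete"] = complete
        rows.append(row)
    return pd.DataFrame(rows)


def rm_anova_2x2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ANOVA via single-df contrasts on the cell means.

    For each effect, per-participant contrast scores are the +-1-weighted sum
    of that participant's 8 cell means (divided by 4 so mains read as simple
    differences of level means). ``F(1, N-1) = N * mean(contrast)^2 /
    var(contrast)``, with p from the F distribution. Effects with zero
    contrast variance are flagged (``F`` NaN, ``flagged`` True).

    Returns a DataFrame with columns effect, F, df1, df2, p, flagged.
    """
    sub = cells.loc[cells["complete"]]
    n = len(sub)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete participants, got {n}")
    labels = [_cell_label(c) for c in CELLS]
    m = sub[labels].to_numpy(dtype=float)  # (N, 8)

    out = []
    for effect in EFFECTS:
        w = _contrast_weights(effect) / 4.0
        scores = m @ w
        var = float(np.var(scores, ddof=1))
        if var == 0.0:
            out.append({"effect": effect, "F": np.nan, "df1": 1, "df2": n - 1,
                        "p": np.nan, "flagged": True})
            continue
        f_val = n * float(np.mean(scores)) ** 2 / var
        p = float(stats.f.sf(f_val, 1, n - 1))
        out.append({"effect": effect, "F": f_val, "df1": 1, "df2": n - 1,
                    "p": p, "flagged": False})
    return pd.DataFrame(out)


class SequenceAnova(BaseEstimator):
    """Scikit-learn-style wrapper: ``fit(trials)`` computes the cell means
    and the seven F tests for one measure.

    Fitted attributes: ``cell_means_`` (per-participant table),
    ``anova_table_`` (effect, F, df1, df2, p), ``n_complete_``.
    """

    def __init__(self, measure: str = "mt"):
        self.measure = measure

    def fit(self, X: pd.DataFrame, y=None):
        self.cell_means_ = cell_means(X, self.measure)
        self.anova_table_ = rm_anova_2x2x2(self.cell_means_)
        self.n_complete_ = int(self.cell_means_["complete"].sum())
        return self
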