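"""Synthetic reaching congruency-task data with known true reliability.

The generator realizes a dual-process effect structure. Initiation time (IT)
reflects response-threshold adjustment: it carries a main effect of the
current trial's congruency and of the previous trial's congruency. Movement
time (MT) reflects online conflict resolution: its congruency effect is
boosted specifically on incongruent trials that follow a congruent trial and
repeat the previous response (cI-r trials), and partial-error trials pay an
in-flight correction cost. Every participant draws baselines and effect
coefficients from between-participant normal distributions, so the congruency
effect of each temporal measure has a known true-score variance and hence a
known true reliability — the quantity the permutation split-half estimator is
supposed to recover.

Times are generated in milliseconds and truncated at 1 ms by resampling the
trial noise. In ``mode="trajectory"`` each trial additionally receives a raw
reach path consistent with its IT/MT: straight to the chosen target on clean
trials, committed toward the wrong target for a fraction of the movement and
then redirected on partial-error trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import Geometry, SimulationConfig
from .errors import GeometryError, UndefinedReliabilityError
from .trajectory_metrics import Trajectory

__all__ = [
    "ParticipantParams",
    "SimulatedDataset",
    "sample_participant_effects",
    "simulate_dataset",
    "synthesize_trajectory",
    "true_reliability",
]

TRIAL_COLUMNS = [
    "participant_id", "age_group", "condition_id", "block", "trial_index",
    "congruency", "target_side", "response_side", "accuracy",
    "it_ms", "mt_ms", "rt_ms", "partial_error", "commitment_fraction",
]


@dataclass(frozen=True)
class ParticipantParams:
    """One participant's realized random effects (ms unless noted)."""

    participant_id: str
    it_baseline: float
    mt_baseline: float
    it_congruency: float
    it_prev_congruency: float
    mt_congruency: float
    mt_cIr_boost: float
    partial_error_prob_incongruent: float
    partial_error_prob_congruent: float
    overt_error_prob_incongruent: float
    overt_error_prob_congruent: float


class SimulatedDataset(NamedTuple):
    """Trial table plus (in trajectory mode) a trial_uid -> Trajectory store."""

    trials: pd.DataFrame
    trajectories: dict[str, Trajectory] | None


def _pid(i: int) -> str:
    return f"p{i + 1:03d}"


def sample_participant_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> list[ParticipantParams]:
    """Draw each participant's baselines and effect coefficients.

    Coefficients come from normal distributions with the configured
    between-participant means and SDs; error probabilities are shared
    constants from the config. Deterministic given the generator state.
    """
    config.validate()
    n = config.n_participants
    draw = lambda m, s: rng.normal(m, s, size=n)  # noqa: E731
    it_base = draw(config.it_baseline_mean, config.it_baseline_sd)
    mt_base = draw(config.mt_baseline_mean, config.mt_baseline_sd)
    a = draw(config.it_congruency_mean, config.it_congruency_sd)
    b = draw(config.it_prev_congruency_mean, config.it_prev_congruency_sd)
    c = draw(config.mt_congruency_mean, config.mt_congruency_sd)
    g = draw(config.mt_cIr_boost_mean, config.mt_cIr_boost_sd)
    return [
        ParticipantParams(
            participant_id=_pid(i),
            it_baseline=float(it_base[i]),
            mt_baseline=float(mt_base[i]),
            it_congruency=float(a[i]),
            it_prev_congruency=float(b[i]),
            mt_congruency=float(c[i]),
            mt_cIr_boost=float(g[i]),
            partial_error_prob_incongruent=config.partial_error_prob_incongruent,
            partial_error_prob_congruent=config.partial_error_prob_congruent,
            overt_error_prob_incongruent=config.overt_error_prob_incongruent,
            overt_error_prob_congruent=config.overt_error_prob_congruent,
        )
        for i in range(n)
    ]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, low: float, high: float
) -> np.ndarray:
    """Resample out-of-range draws; degenerate sd=0 falls back to clipping."""
    x = rng.normal(mean, sd, size=size)
    if sd == 0:
        return np.clip(x, low, high)
    bad = (x <= low) | (x >= high)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x <= low) | (x >= high)
    return x


def _positive_times(rng: np.random.Generator, loc: np.ndarray, sd: float) -> np.ndarray:
    """loc + N(0, sd) with resampling of the noise until every time >= 1 ms."""
    t = loc + rng.normal(0.0, sd, size=loc.shape)
    bad = t < 1.0
    guard = 0
    while bad.any():
        t[bad] = loc[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
        bad = t < 1.0
        guard += 1
        if guard > 10_000:  # pathological config (baseline far below zero)
            t[bad] = 1.0
            break
    return t


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the trial table (and trajectories when ``mode='trajectory'``).

    Per trial, with participant coefficients (a, b, c, g):

    * ``IT = it_baseline + a*[n=I] + b*[n-1=I] + noise``
    * ``MT = mt_baseline + c*[n=I] + g*[n=I and n-1=C and response repetition]
      + correction_cost_ms * commitment_fraction * [partial error] + noise``
    * ``RT = IT + MT``

    Each block holds equal numbers of congruent and incongruent trials in
    randomized order; target sides are random, so response repetitions arise
    naturally at ~50%. The first trial of each block carries no previous-trial
    terms. Overt errors flip the response side. All times are >= 1 ms.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = sample_participant_effects(config, rng)

    frames = []
    traj_specs = []  # (uid, it, mt, response_side, partial, fraction)
    tpb = config.trials_per_block
    half = tpb // 2
    base_cong = np.array(["C"] * half + ["I"] * half)

    for p in params:
        n_trials = config.n_blocks * tpb
        cong = np.empty(n_trials, dtype="<U1")
        for blk in range(config.n_blocks):
            cong[blk * tpb:(blk + 1) * tpb] = rng.permutation(base_cong)
        is_inc = cong == "I"

        target = np.where(rng.random(n_trials) < 0.5, "L", "R")
        p_err = np.where(is_inc, p.overt_error_prob_incongruent,
                         p.overt_error_prob_congruent)
        flip = rng.random(n_trials) < p_err
        response = np.where(flip, np.where(target == "L", "R", "L"), target)
        accuracy = np.where(flip, "error", "correct")

        block = np.repeat(np.arange(1, config.n_blocks + 1), tpb)
        trial_index = np.tile(np.arange(1, tpb + 1), config.n_blocks)
        first = trial_index == 1

        prev_inc = np.zeros(n_trials, dtype=bool)
        prev_inc[1:] = is_inc[:-1]
        prev_inc[first] = False
        prev_cong_flag = np.zeros(n_trials, dtype=bool)  # previous trial congruent
        prev_cong_flag[1:] = ~is_inc[:-1]
        prev_cong_flag[first] = False
        repetition = np.zeros(n_trials, dtype=bool)
        repetition[1:] = response[1:] == response[:-1]
        repetition[first] = False

        cIr = is_inc & prev_cong_flag & repetition

        p_partial = np.where(is_inc, p.partial_error_prob_incongruent,
                             p.partial_error_prob_congruent)
        partial = rng.random(n_trials) < p_partial
        fraction = np.full(n_trials, np.nan)
        if partial.any():
            fraction[partial] = _truncated_normal(
                rng, config.commitment_fraction_mean, config.commitment_fraction_sd,
                int(partial.sum()), 0.0, 1.0,
            )

        it_loc = (p.it_baseline + p.it_congruency * is_inc
                  + p.it_prev_congruency * prev_inc)
        it = _positive_times(rng, it_loc, config.it_noise_sd)
        mt_loc = (p.mt_baseline + p.mt_congruency * is_inc + p.mt_cIr_boost * cIr
                  + config.correction_cost_ms * np.where(partial, fraction, 0.0))
        mt = _positive_times(rng, mt_loc, config.mt_noise_sd)

        frames.append(pd.DataFrame({
            "participant_id": p.participant_id,
            "age_group": "adult",
            "condition_id": "simulated",
            "block": block,
            "trial_index": trial_index,
            "congruency": cong,
            "target_side": target,
            "response_side": response,
            "accuracy": accuracy,
            "it_ms": it,
            "mt_ms": mt,
            "rt_ms": it + mt,
            "partial_error": partial,
            "commitment_fraction": fraction,
        }))
        if config.mode == "trajectory":
            uids = [f"{p.participant_id}_b{b_}_t{t_}"
                    for b_, t_ in zip(block, trial_index)]
            traj_specs.extend(
                zip(uids, it, mt, response, partial, fraction)
            )

    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]

    trajectories = None
    if config.mode == "trajectory":
        trajectories = {}
        for uid, it_, mt_, side, part, frac in traj_specs:
            trajectories[uid] = synthesize_trajectory(
                trial_uid=uid, it_ms=float(it_), mt_ms=float(mt_),
                response_side=side, partial_error=bool(part),
                commitment_fraction=float(frac) if part else 0.0,
                geometry=config.geometry, sampling_rate=config.sampling_rate,
                onset_jitter_sd=config.onset_jitter_sd, rng=rng,
            )
    return SimulatedDataset(trials=trials, trajectories=trajectories)


def synthesize_trajectory(
    trial_uid: str,
    it_ms: float,
    mt_ms: float,
    response_side: str,
    partial_error: bool,
    commitment_fraction: float,
    geometry: Geometry,
    sampling_rate: float,
    onset_jitter_sd: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Construct a raw reach path consistent with a trial's IT and MT.

    The hand sits at the start point (plus Gaussian jitter) until ``it_ms``,
    then moves with constant velocity: directly to the selected target on
    clean trials, or toward the *wrong* target for ``commitment_fraction`` of
    the movement and then straight to the selected target on partial-error
    trials. Positional jitter is windowed to vanish at movement onset and at
    target contact, so the final sample coincides exactly with the target.
    """
    geometry.validate()
    start = np.asarray(geometry.start, dtype=float)
    target = np.asarray(geometry.target(response_side), dtype=float)
    wrong = np.asarray(
        geometry.target("L" if response_side == "R" else "R"), dtype=float
    )
    if np.allclose(start, target):
        raise GeometryError(f"{trial_uid}: start coincides with target")

    dt = 1000.0 / sampling_rate
    total = it_ms + mt_ms
    # sample grid restarts at movement onset so one sample lands exactly on
    # it_ms; onset is then recoverable to within one sample period
    t = np.concatenate([np.arange(0.0, it_ms, dt), it_ms + np.arange(0.0, mt_ms, dt)])
    if t.size == 0 or t[-1] < total:
        t = np.append(t, total)

    pos = np.empty((t.size, 2))
    pre = t < it_ms
    pos[pre] = start + rng.normal(0.0, onset_jitter_sd, size=(int(pre.sum()), 2))

    tau = np.clip((t[~pre] - it_ms) / mt_ms, 0.0, 1.0)
    if partial_error and commitment_fraction > 0.0:
        f = commitment_fraction
        turn = start + f * (wrong - start)
        early = tau <= f
        path = np.empty((tau.size, 2))
        path[early] = start + np.outer(tau[early], wrong - start)
        path[~early] = turn + np.outer((tau[~early] - f) / (1.0 - f), target - turn)
    else:
        path = start + np.outer(tau, target - start)
    # window: zero jitter at onset and at contact, so endpoints are exact
    window = 4.0 * tau * (1.0 - tau)
    jitter = rng.normal(0.0, onset_jitter_sd, size=(tau.size, 2)) * window[:, None]
    pos[~pre] = path + jitter
    pos[-1] = target

    return Trajectory(
        trial_uid=trial_uid, t=t, xy=pos, start_point=start, end_point=target
    )


def true_reliability(
    config: SimulationConfig,
    n_retained_per_condition: int | tuple[int, int],
) -> dict[str, float]:
    """Closed-form full-length reliability of each temporal congruency effect.

    With between-participant effect variance tau^2 and within-participant
    trial-noise variance sigma^2, the reliability of the congruency-effect
    difference score computed from n_C congruent and n_I incongruent retained
    trials is ``tau^2 / (tau^2 + sigma^2 * (1/n_C + 1/n_I))``. This is the
    full-length quantity the Spearman-Brown-corrected split-half estimator
    targets. Exact when the nuisance effects (previous-trial congruency,
    cI-r boost, partial-error correction cost) are zero; otherwise those
    terms add trial-level variance the formula does not model.

    Returns a dict keyed ``{"it", "mt", "rt"}``.
    """
    if isinstance(n_retained_per_condition, tuple):
        n_c, n_i = n_retained_per_condition
    else:
        n_c = n_i = int(n_retained_per_condition)
    if n_c < 1 or n_i < 1:
        raise ValueError("n_retained_per_condition must be >= 1")
    harm = 1.0 / n_c + 1.0 / n_i

    out = {}
    components = {
        "it": (config.it_congruency_sd ** 2, config.it_noise_sd ** 2),
        "mt": (config.mt_congruency_sd ** 2, config.mt_noise_sd ** 2),
        "rt": (
            config.it_congruency_sd ** 2 + config.mt_congruency_sd ** 2,
            config.it_noise_sd ** 2 + config.mt_noise_sd ** 2,
        ),
    }
    for measure, (tau2, sigma2) in components.items():
        if tau2 == 0.0 and sigma2 == 0.0:
            raise UndefinedReliabilityError(
                f"{measure}: tau^2 = sigma^2 = 0, reliability undefined"
            )
        out[measure] = tau2 / (tau2 + sigma2 * harm)
    return out
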