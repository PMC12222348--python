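"""Shared fixtures: synthetic configs and toy trial tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splitreach import SimulationConfig, code_conditions, filter_trials, simulate_dataset


def clean_config(
    tau: float = 36.0,
    sigma: float = 60.0,
    n_participants: int = 100,
    n_blocks: int = 4,
    trials_per_block: int = 42,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Config whose IT congruency effect has exactly the (tau, sigma)
    variance components: every nuisance effect (previous-trial congruency,
    cI-r boost, partial/overt errors) is switched off so the closed-form
    true reliability is exact."""
    kwargs = dict(
        n_participants=n_participants,
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        it_congruency_mean=30.0,
        it_congruency_sd=tau,
        it_noise_sd=sigma,
        it_prev_congruency_mean=0.0,
        it_prev_congruency_sd=0.0,
        mt_cIr_boost_mean=0.0,
        mt_cIr_boost_sd=0.0,
        partial_error_prob_incongruent=0.0,
        partial_error_prob_congruent=0.0,
        overt_error_prob_incongruent=0.0,
        overt_error_prob_congruent=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def null_config(n_participants: int = 24, trials_per_block: int = 24,
                n_blocks: int = 2, seed: int = 0) -> SimulationConfig:
    """No true effects anywhere: every effect mean and SD is zero, only
    baselines and trial noise remain."""
    return SimulationConfig(
        n_participants=n_participants, n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        it_congruency_mean=0.0, it_congruency_sd=0.0,
        it_prev_congruency_mean=0.0, it_prev_congruency_sd=0.0,
        mt_congruency_mean=0.0, mt_congruency_sd=0.0,
        mt_cIr_boost_mean=0.0, mt_cIr_boost_sd=0.0,
        partial_error_prob_incongruent=0.0, partial_error_prob_congruent=0.0,
        overt_error_prob_incongruent=0.0, overt_error_prob_congruent=0.0,
        seed=seed,
    )


def retained_from(config: SimulationConfig) -> pd.DataFrame:
    trials = simulate_dataset(config).trials
    retained, _ = filter_trials(code_conditions(trials))
    return retained


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a trial table from terse row dicts, filling boilerplate."""
    defaults = dict(
        participant_id="p001", age_group="adult", condition_id="test",
        block=1, congruency="C", target_side="L", response_side="L",
        accuracy="correct", it_ms=300.0, mt_ms=300.0,
    )
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, "trial_index": i + 1, **row}
        if "rt_ms" not in r:
            r["rt_ms"] = r["it_ms"] + r["mt_ms"]
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_retained() -> pd.DataFrame:
    """12 participants, 2 blocks x 16 trials, defaults; coded and filtered."""
    return retained_from(SimulationConfig(
        n_participants=12, n_blocks=2, trials_per_block=16, seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
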