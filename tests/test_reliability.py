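"""Spearman-Brown arithmetic, split mechanics, permutation aggregation,
exhaustive-enumeration oracle, and the analytic difference-score identity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitreach import (
    SplitHalfReliability,
    analytic_difference_reliability,
    classify_reliability,
    difference_score_reliability_analytic,
    permutation_reliability,
    spearman_brown,
    split_half_once,
    true_reliability,
)
from splitreach.errors import EstimationError

from conftest import clean_config, make_trials, retained_from


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [
        (0.5, 2 / 3), (1.0, 1.0), (0.0, 0.0), (-1 / 3, -1.0),
    ])
    def test_arithmetic(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_invalid_below_minus_one(self):
        assert np.isnan(spearman_brown(-1.0))
        assert np.isnan(spearman_brown(-1.5))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.999, 1.0), st.floats(-0.999, 1.0))
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert spearman_brown(lo) < spearman_brown(hi)


class TestClassifyReliability:
    @pytest.mark.parametrize("r,label", [
        (0.69, "poor"), (0.70, "acceptable"), (0.79, "acceptable"),
        (0.80, "good"), (0.894, "good"), (0.90, "excellent"),
        (0.95, "excellent"), (-0.2, "poor"),
    ])
    def test_cutoffs(self, r, label):
        assert classify_reliability(r) == label


def two_cell_table(values: dict[str, tuple[list, list]]) -> pd.DataFrame:
    rows = []
    for pid, (v_c, v_i) in values.items():
        for v in v_c:
            rows.append({"participant_id": pid, "congruency": "C",
                         "it_ms": v / 2, "mt_ms": v / 2})
        for v in v_i:
            rows.append({"participant_id": pid, "congruency": "I",
                         "it_ms": v / 2, "mt_ms": v / 2})
    # give every participant their own block to keep trial keys unique
    df = make_trials(rows)
    df["trial_index"] = range(1, len(df) + 1)
    return df


class TestSplitMechanics:
    def test_noiseless_data_every_split_perfect(self):
        cfg = clean_config(tau=36.0, sigma=0.0, n_participants=12,
                           n_blocks=1, trials_per_block=16, seed=1)
        retained = retained_from(cfg)
        r = split_half_once(retained, "it", rng=0)
        assert r == pytest.approx(1.0)
        est = permutation_reliability(retained, "it", n_permutations=200, seed=0)
        assert est.mean_r_sb == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0)
        assert est.label == "excellent"

    def test_minimal_two_trials_per_cell(self):
        values = {f"p{i}": ([500.0 + 10 * i, 520.0 + 9 * i],
                            [600.0 + 25 * i, 610.0 + 23 * i]) for i in range(6)}
        est = permutation_reliability(two_cell_table(values), "rt",
                                      n_permutations=100, seed=3)
        assert np.isfinite(est.mean_r_sb)

    def test_determinism(self):
        values = {f"p{i}": (list(500 + np.arange(4.0) * i),
                            list(600 + np.arange(4.0) * 2 * i)) for i in range(8)}
        df = two_cell_table(values)
        a = permutation_reliability(df, "rt", n_permutations=300, seed=11)
        b = permutation_reliability(df, "rt", n_permutations=300, seed=11)
        assert a == b

    def test_too_few_participants(self):
        values = {"p0": ([1.0, 2.0], [3.0, 4.0]), "p1": ([1.0, 2.0], [3.0, 5.0])}
        with pytest.raises(EstimationError):
            permutation_reliability(two_cell_table(values), "rt", seed=0)

    def test_participants_below_min_trials_dropped(self):
        values = {f"p{i}": ([500.0, 510.0 + i], [600.0, 640.0 + 3 * i])
                  for i in range(5)}
        values["p9"] = ([500.0], [600.0, 610.0])  # only 1 congruent trial
        est = permutation_reliability(two_cell_table(values), "rt",
                                      n_permutations=50, seed=0)
        assert est.n_participants_used == 5

    def test_estimator_class_wraps_function(self):
        values = {f"p{i}": (list(500 + np.arange(4.0) * i),
                            list(600 + np.arange(4.0) * 2 * i)) for i in range(8)}
        df = two_cell_table(values)
        model = SplitHalfReliability(measure="rt", n_permutations=200, seed=5).fit(df)
        direct = permutation_reliability(df, "rt", n_permutations=200, seed=5)
        assert model.mean_r_sb_ == direct.mean_r_sb
        assert model.ci_ == (direct.ci_low, direct.ci_high)
        assert model.get_params()["n_permutations"] == 200


def exhaustive_mean_r_sb(values: dict[str, tuple[list, list]],
                         score_type: str = "difference") -> float:
    """Exact mean Spearman-Brown-corrected r over ALL joint half-splits.

    Only feasible for 2 trials per cell (each cell has exactly 2 distinct
    half-assignments); enumerates the full product space.
    """
    pids = sorted(values)
    cell_options = []  # per participant: list of (score1, score2) options
    for pid in pids:
        v_c, v_i = (np.asarray(values[pid][0]), np.asarray(values[pid][1]))
        opts = []
        for pick_c, pick_i in itertools.product(range(2), range(2)):
            c1, c2 = v_c[pick_c], v_c[1 - pick_c]
            i1, i2 = v_i[pick_i], v_i[1 - pick_i]
            if score_type == "difference":
                opts.append((i1 - c1, i2 - c2))
            elif score_type == "congruent_component":
                opts.append((c1, c2))
            else:
                opts.append((i1, i2))
        cell_options.append(opts)
    r_sbs = []
    for combo in itertools.product(*cell_options):
        s1 = np.array([c[0] for c in combo])
        s2 = np.array([c[1] for c in combo])
        if np.std(s1) == 0 or np.std(s2) == 0:
            continue
        r = np.corrcoef(s1, s2)[0, 1]
        if r > -1:
            r_sbs.append(2 * r / (1 + r))
    return float(np.mean(r_sbs))


class TestExhaustiveOracle:
    def test_vectorized_engine_matches_enumeration(self, rng):
        # 3 participants x 2 trials/cell: the joint split space has
        # (2*2)^3 = 64 assignments, enumerable exactly
        values = {f"p{i}": (list(rng.normal(500, 30, 2)),
                            list(rng.normal(600, 30, 2))) for i in range(3)}
        exact = exhaustive_mean_r_sb(values)
        df = two_cell_table(values)
        n_perm = 4000
        est = permutation_reliability(df, "rt", n_permutations=n_perm, seed=17)
        # Monte-Carlo SE of the mean over splits
        naive = [split_half_once(df, "rt", rng=np.random.default_rng(1000 + k))
                 for k in range(1500)]
        naive = [x for x in naive if np.isfinite(x)]
        sd = np.std(naive, ddof=1)
        assert abs(est.mean_r_sb - exact) < 3 * sd / np.sqrt(n_perm) + 1e-3
        assert abs(np.mean(naive) - exact) < 3 * sd / np.sqrt(len(naive))


class TestAnalyticIdentity:
    def test_reliable_components_unreliable_difference(self):
        # components at 0.9 reliability correlated 0.8 with equal SDs leave
        # only 0.5 for the difference score
        assert difference_score_reliability_analytic(
            0.9, 0.9, 0.8, 10.0, 10.0) == pytest.approx(0.5)

    def test_independent_components_weighted_mean(self):
        r = difference_score_reliability_analytic(0.9, 0.6, 0.0, 20.0, 10.0)
        assert r == pytest.approx((0.9 * 400 + 0.6 * 100) / 500)

    def test_identical_components_undefined(self):
        with pytest.raises(ZeroDivisionError):
            difference_score_reliability_analytic(0.9, 0.9, 1.0, 10.0, 10.0)

    def test_analytic_matches_permutation_on_synthetic_data(self):
        cfg = clean_config(tau=36.0, sigma=60.0, n_participants=80,
                           n_blocks=2, trials_per_block=40, seed=21)
        retained = retained_from(cfg)
        direct = permutation_reliability(retained, "it",
                                         n_permutations=1000, seed=1)
        analytic, parts = analytic_difference_reliability(
            retained, "it", n_permutations=1000, seed=2)
        assert abs(analytic - direct.mean_r_sb) < 0.05
        assert parts["r_congruent"] > direct.mean_r_sb


class TestRecoveryProperties:
    def test_monotone_refinement_in_trial_count(self):
        # expected reliability never decreases with more trials per cell
        means = []
        for tpb in (8, 24, 72):
            ests = []
            for seed in (0, 1, 2):
                cfg = clean_config(tau=30.0, sigma=70.0, n_participants=60,
                                   n_blocks=1, trials_per_block=tpb, seed=seed)
                ests.append(permutation_reliability(
                    retained_from(cfg), "it", n_permutations=400,
                    seed=seed).mean_r_sb)
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]

    def test_component_exceeds_difference_reliability(self, small_retained):
        # shared baselines make component scores far more reliable than the
        # difference score on adult-like defaults
        comp = permutation_reliability(small_retained, "rt",
                                       "congruent_component",
                                       n_permutations=400, seed=0)
        diff = permutation_reliability(small_retained, "rt", "difference",
                                       n_permutations=400, seed=0)
        assert comp.mean_r_sb > diff.mean_r_sb

    def test_recovery_of_true_reliability_single_config(self):
        cfg = clean_config(tau=36.0, sigma=60.0, n_participants=100,
                           n_blocks=4, trials_per_block=42, seed=31)
        retained = retained_from(cfg)
        n_c = (retained.congruency == "C").groupby(retained.participant_id).size().mean()
        n_i = (retained.congruency == "I").groupby(retained.participant_id).size().mean()
        target = true_reliability(cfg, (int(round(n_c)), int(round(n_i))))["it"]
        est = permutation_reliability(retained, "it", n_permutations=1000, seed=1)
        assert abs(est.mean_r_sb - target) < 0.05
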