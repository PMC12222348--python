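"""Cell means and the contrast-based 2x2x2 repeated-measures ANOVA, with
independent oracles (paired t, statsmodels AnovaRM, pingouin)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splitreach import (
    SequenceAnova,
    cell_means,
    code_conditions,
    filter_trials,
    rm_anova_2x2x2,
    simulate_dataset,
)
from splitreach.config import SimulationConfig
from splitreach.errors import InsufficientDataError
from splitreach.sequence_anova import CELLS, EFFECTS, _cell_label

from conftest import make_trials


def cells_frame(means: np.ndarray) -> pd.DataFrame:
    """Wrap an (N, 8) cell-means array in the table rm_anova_2x2x2 expects."""
    labels = [_cell_label(c) for c in CELLS]
    df = pd.DataFrame(means, columns=labels)
    df.insert(0, "participant_id", [f"p{i}" for i in range(len(df))])
    for lbl in labels:
        df[f"n_{lbl}"] = 4
    df["complete"] = True
    return df


def coded_simulated(seed=0, n=40):
    cfg = SimulationConfig(n_participants=n, n_blocks=2, trials_per_block=48,
                           seed=seed)
    coded = code_conditions(simulate_dataset(cfg).trials)
    retained, _ = filter_trials(coded)
    return retained


class TestCellMeans:
    def test_single_trial_cells_equal_trial_values(self):
        # 9-trial sequence whose trials 2..9 visit each of the 8 cells exactly
        # once: consecutive congruency pairs form an Eulerian circuit covering
        # each (prev, current) pair twice, once per repetition type
        cong_seq = list("CCCIIICIC")
        rep_seq = [None, "repetition", "alternation", "repetition",
                   "repetition", "alternation", "repetition",
                   "alternation", "alternation"]
        rows, resp, expected = [], "L", {}
        for i, cong in enumerate(cong_seq):
            if i > 0:
                if rep_seq[i] == "alternation":
                    resp = "L" if resp == "R" else "R"
                prev = "c" if cong_seq[i - 1] == "C" else "i"
                expected[_cell_label((cong, prev, rep_seq[i]))] = 100.0 * i
            rows.append({"congruency": cong, "response_side": resp,
                         "target_side": resp, "it_ms": 50.0 * i or 25.0,
                         "mt_ms": 50.0 * i or 25.0})
        assert len(expected) == 8
        coded = code_conditions(make_trials(rows))
        table = cell_means(coded, "rt")
        assert len(table) == 1
        row = table.iloc[0]
        for label, v in expected.items():
            assert row[label] == v
        assert row.complete

    def test_balanced_design_counts(self):
        retained = coded_simulated(seed=2)
        table = cell_means(retained, "mt")
        labels = [f"n_{_cell_label(c)}" for c in CELLS]
        counts = table[labels].to_numpy(dtype=float).mean(axis=0)
        # randomized congruency and ~50% repetitions spread trials evenly
        assert counts.min() > 0.5 * counts.max()

    def test_incomplete_participants_flagged(self):
        rows = [{"congruency": "C", "response_side": "L"},
                {"congruency": "C", "response_side": "L"},
                {"congruency": "I", "response_side": "L"}]
        coded = code_conditions(make_trials(rows))
        table = cell_means(coded, "rt")
        assert not table.iloc[0].complete


class TestRmAnova:
    def test_f_equals_paired_t_squared(self, rng):
        # oracle: the congruency main effect F must equal the squared paired
        # t comparing I-cell and C-cell averages, participant by participant
        m = rng.normal(500, 40, size=(6, 8))
        m[:, 4:] += rng.normal(30, 10, size=(6, 1))  # I cells get an effect
        table = rm_anova_2x2x2(cells_frame(m))
        i_avg = m[:, 4:].mean(axis=1)
        c_avg = m[:, :4].mean(axis=1)
        t, p = stats.ttest_rel(i_avg, c_avg)
        row = table.set_index("effect").loc["congruency"]
        assert row.F == pytest.approx(t ** 2)
        assert row.p == pytest.approx(p)
        assert (row.df1, row.df2) == (1, 5)

    def test_zero_contrast_variance_flagged(self):
        m = np.tile(np.arange(8.0) * 10, (5, 1))  # identical across subjects
        table = rm_anova_2x2x2(cells_frame(m)).set_index("effect")
        assert table.loc["congruency", "flagged"]
        assert np.isnan(table.loc["congruency", "F"])

    def test_sign_flip_leaves_f_unchanged(self, rng):
        m = rng.normal(400, 30, size=(8, 8))
        base = rm_anova_2x2x2(cells_frame(m)).set_index("effect")["F"]
        # swap the repetition/alternation levels: permute columns accordingly
        labels = [_cell_label(c) for c in CELLS]
        swapped_labels = [
            _cell_label((cong, prev,
                         "alternation" if rep == "repetition" else "repetition"))
            for cong, prev, rep in CELLS
        ]
        frame = cells_frame(m)
        frame[labels] = frame[swapped_labels].to_numpy()
        flipped = rm_anova_2x2x2(frame).set_index("effect")["F"]
        for eff in EFFECTS:
            assert flipped[eff] == pytest.approx(base[eff])

    def test_needs_three_complete_participants(self, rng):
        frame = cells_frame(rng.normal(400, 30, size=(4, 8)))
        frame.loc[2:, "complete"] = False
        with pytest.raises(InsufficientDataError):
            rm_anova_2x2x2(frame)

    def test_matches_statsmodels_anovarm(self):
        # independent cross-validation of all 7 effects on simulated data
        from statsmodels.stats.anova import AnovaRM

        retained = coded_simulated(seed=5, n=20)
        model = SequenceAnova("mt").fit(retained)
        cm = model.cell_means_.loc[model.cell_means_["complete"]]
        long = []
        for _, row in cm.iterrows():
            for cell in CELLS:
                long.append({"pid": row.participant_id,
                             "cong": cell[0], "prev": cell[1], "rep": cell[2],
                             "y": row[_cell_label(cell)]})
        res = AnovaRM(pd.DataFrame(long), "y", "pid",
                      within=["cong", "prev", "rep"]).fit().anova_table
        mapping = {
            "congruency": "cong", "prev_congruency": "prev",
            "repetition": "rep",
            "congruency:prev_congruency": "cong:prev",
            "congruency:repetition": "cong:rep",
            "prev_congruency:repetition": "prev:rep",
            "congruency:prev_congruency:repetition": "cong:prev:rep",
        }
        ours = model.anova_table_.set_index("effect")
        for eff, sm_name in mapping.items():
            assert ours.loc[eff, "F"] == pytest.approx(
                res.loc[sm_name, "F Value"], rel=1e-6)

    def test_matches_pingouin_two_way(self):
        # collapse the repetition factor and check the 2x2 against pingouin
        import pingouin as pg

        retained = coded_simulated(seed=6, n=16)
        sub = retained[retained.prev_congruency.isin(["c", "i"])]
        agg = (sub.groupby(["participant_id", "congruency", "prev_congruency"])
               ["mt_ms"].mean().reset_index())
        res = pg.rm_anova(data=agg, dv="mt_ms",
                          within=["congruency", "prev_congruency"],
                          subject="participant_id", detailed=True)
        # our contrast F for the interaction, from the same aggregated means
        wide = agg.pivot_table(index="participant_id",
                               columns=["congruency", "prev_congruency"],
                               values="mt_ms")
        contrast = (wide[("I", "i")] - wide[("I", "c")]
                    - wide[("C", "i")] + wide[("C", "c")]) / 2.0
        n = len(contrast)
        f_ours = n * contrast.mean() ** 2 / contrast.var(ddof=1)
        f_pg = res.set_index("Source").loc["congruency * prev_congruency", "F"]
        assert f_ours == pytest.approx(f_pg, rel=1e-6)

    def test_cIr_boost_drives_three_way_interaction(self):
        cfg = SimulationConfig(seed=12)  # study-calibrated defaults, N=51
        coded = code_conditions(simulate_dataset(cfg).trials)
        retained, _ = filter_trials(coded)
        mt = SequenceAnova("mt").fit(retained).anova_table_.set_index("effect")
        it = SequenceAnova("it").fit(retained).anova_table_.set_index("effect")
        assert mt.loc["congruency:prev_congruency:repetition", "p"] < 0.05
        assert it.loc["congruency", "p"] < 0.05
        assert it.loc["prev_congruency", "p"] < 0.05
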