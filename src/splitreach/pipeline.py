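"""Pipeline driver: simulate or ingest, extract, filter, score, estimate.

``run_pipeline`` executes the full stage order — simulate/ingest, optional
trajectory measure extraction, condition coding, the exclusion ladder,
optional log transform, participant effects and descriptives, permutation
split-half reliability, and the 2x2x2 sequence ANOVA — writing one CSV per
stage plus a run manifest (config, seed, package versions, exclusion totals)
so every output is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import splitreach

from .config import PipelineConfig
from .effects import component_correlation, describe_effects, participant_condition_means
from .errors import SplitreachError
from .io import read_trajectories, read_trial_table, write_trajectories, write_trial_table
from .preprocessing import ConditionCoder, TrialFilter, LogTransformer
from .reliability import permutation_reliability
from .sequence_anova import SequenceAnova
from .synthetic_data import simulate_dataset
from .trajectory_metrics import extract_measures_batch

__all__ = ["run_pipeline"]

logger = logging.getLogger("splitreach")

_TEMPORAL = ("rt", "it", "mt")


def _trial_uid(df: pd.DataFrame) -> pd.Series:
    return (df["participant_id"].astype(str) + "_b" + df["block"].astype(str)
            + "_t" + df["trial_index"].astype(str))


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, SplitreachError):
                raise SplitreachError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, SplitreachError):
                exc.args = (f"stage {name!r}: {exc}",)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle as a dict of DataFrames /
    records and writes every table under ``config.output_dir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, str(config.log_level).upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # -- ingest / simulate --------------------------------------------
    trajectories = None
    with _stage("ingest"):
        if config.simulation is not None:
            sim = simulate_dataset(config.simulation)
            trials, trajectories = sim.trials, sim.trajectories
        else:
            trials = read_trial_table(config.trial_csv)
            if config.trajectory_csv is not None:
                trajectories = read_trajectories(config.trajectory_csv)

    # -- trajectory measure extraction --------------------------------
    if trajectories is not None:
        with _stage("extract_measures"):
            measures = extract_measures_batch(trajectories)
            uid = _trial_uid(trials)
            merged = trials.assign(trial_uid=uid).merge(
                measures.rename(columns={
                    "it_ms": "it_traj", "mt_ms": "mt_traj",
                    "rt_ms": "rt_traj"}),
                on="trial_uid", how="left",
            )
            merged["curv"] = merged["curv"].astype(float)
            for col in ("it_ms", "mt_ms", "rt_ms"):
                if col not in merged.columns or merged[col].isna().all():
                    merged[col] = merged[f"{col.split('_')[0]}_traj"]
            trials = merged.drop(columns=["it_traj", "mt_traj", "rt_traj", "flag"])
            write_trajectories(trajectories, out / "trajectories.csv")

    measure_list = list(config.measures)
    if trajectories is not None and "curv" not in measure_list:
        measure_list.append("curv")

    # -- condition coding ---------------------------------------------
    with _stage("code_conditions"):
        coded = ConditionCoder().fit_transform(trials)
        write_trial_table(coded, out / "trials_coded.csv")

    # -- filtering ----------------------------------------------------
    with _stage("filter"):
        filt = TrialFilter(config.filter)
        retained = filt.fit_transform(coded)
        exclusion_log = filt.exclusion_log_
        exclusion_log.to_csv(out / "exclusion_log.csv", index=False)
        write_trial_table(retained, out / "trials_retained.csv")
        logger.info("retained %d of %d trials", len(retained), len(coded))

        # error-rate effects use the bounds-filtered, accuracy-unfiltered table
        acc_cfg = dataclasses.replace(
            config.filter, exclude_errors=False, exclude_post_error=False)
        accuracy_table = TrialFilter(acc_cfg).fit_transform(coded)

    if config.log_transform:
        with _stage("log_transform"):
            cols = tuple(f"{m}_ms" for m in measure_list if m in _TEMPORAL)
            retained = LogTransformer(cols).fit_transform(retained)

    # -- effects ------------------------------------------------------
    with _stage("effects"):
        effect_frames, desc_rows, corr_rows = [], [], []
        for measure in measure_list:
            table = participant_condition_means(
                accuracy_table if measure == "error_rate" else retained, measure)
            effect_frames.append(table)
            ok = table.loc[~table["flagged"], "effect"]
            if len(ok) >= 4:
                d = describe_effects(ok)
                desc_rows.append({"measure": measure, "M": d.m, "SD": d.sd,
                                  "Min": d.min, "Max": d.max, "Skew": d.skew,
                                  "Kurtosis": d.kurtosis, "n": d.n})
            corr_rows.append({"measure": measure,
                              "r_components": component_correlation(table)})
        effects_table = pd.concat(effect_frames, ignore_index=True)
        effects_table.to_csv(out / "participant_effects.csv", index=False)
        pd.DataFrame(desc_rows).to_csv(out / "effect_descriptives.csv", index=False)
        pd.DataFrame(corr_rows).to_csv(out / "component_correlations.csv", index=False)
        bundle["effects"] = effects_table
        bundle["descriptives"] = pd.DataFrame(desc_rows)

    # -- reliability --------------------------------------------------
    with _stage("reliability"):
        ss = np.random.SeedSequence(config.seed)
        rel_rows = []
        for measure in measure_list:
            data = accuracy_table if measure == "error_rate" else retained
            for score_type in config.score_types:
                rng = np.random.default_rng(ss.spawn(1)[0])
                est = permutation_reliability(
                    data, measure, score_type, config.n_permutations,
                    rng, config.min_trials)
                rel_rows.append({
                    "measure": measure, "score_type": score_type,
                    "mean_r_sb": est.mean_r_sb, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "label": est.label,
                    "n_participants": est.n_participants_used,
                    "n_invalid_splits": est.n_invalid_splits,
                    "n_permutations": est.n_permutations,
                    "warning": est.warning or "",
                })
                if est.n_invalid_splits:
                    logger.info("%s/%s: %d invalid splits", measure,
                                score_type, est.n_invalid_splits)
        reliability_table = pd.DataFrame(rel_rows)
        reliability_table.to_csv(out / "reliability.csv", index=False)
        bundle["reliability"] = reliability_table

    # -- sequence ANOVA -----------------------------------------------
    with _stage("anova"):
        anova_frames, cm_frames = [], []
        for measure in measure_list:
            if measure not in _TEMPORAL:
                continue
            model = SequenceAnova(measure).fit(retained)
            anova_frames.append(model.anova_table_.assign(measure=measure))
            cm_frames.append(model.cell_means_.assign(measure=measure))
        anova_table = pd.concat(anova_frames, ignore_index=True)
        anova_table.to_csv(out / "sequence_anova.csv", index=False)
        pd.concat(cm_frames, ignore_index=True).to_csv(
            out / "cell_means.csv", index=False)
        bundle["anova"] = anova_table

    # -- manifest -----------------------------------------------------
    totals = exclusion_log.groupby("rule")["n_removed"].sum().to_dict()
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "splitreach": splitreach.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_trials_input": int(len(coded)),
        "n_trials_retained": int(len(retained)),
        "exclusion_totals": {k: int(v) for k, v in totals.items()},
        "low_trial_participants": list(filt.low_trial_participants_),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    bundle["retained"] = retained
    bundle["exclusion_log"] = exclusion_log
    return bundle
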