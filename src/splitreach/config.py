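"""Configuration objects for simulation, filtering and the pipeline driver.

All times are milliseconds, all positions millimetres, curvature unitless.
Configs are plain dataclasses with explicit validation (``validate()`` raises
:class:`~splitreach.errors.ConfigError` naming the offending field) and can be
round-tripped through YAML/JSON via ``to_dict`` / ``from_dict`` / ``from_file``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .errors import ConfigError

__all__ = ["Geometry", "SimulationConfig", "FilterConfig", "PipelineConfig"]


@dataclass(frozen=True)
class Geometry:
    """Planar reach geometry: a start point and two lateral targets (mm).

    Defaults loosely mirror an upright touchscreen layout: start at the bottom
    centre, response targets up and to either side.
    """

    start: tuple[float, float] = (0.0, 0.0)
    left_target: tuple[float, float] = (-100.0, 280.0)
    right_target: tuple[float, float] = (100.0, 280.0)

    def target(self, side: str) -> tuple[float, float]:
        return self.left_target if side == "L" else self.right_target

    def validate(self) -> None:
        for name in ("left_target", "right_target"):
            tgt = getattr(self, name)
            if tuple(tgt) == tuple(self.start):
                raise ConfigError(f"geometry.{name}: target coincides with start point")


@dataclass
class SimulationConfig:
    """Generative model for a reaching congruency task.

    The model is dual-process: initiation time (IT) carries effects of the
    current and previous trial's congruency, while movement time (MT) carries
    a congruency effect concentrated in congruent-preceded incongruent
    response-repetition (cI-r) trials plus a correction cost on partial-error
    trials. Each participant draws their baselines and effect coefficients
    from normal distributions (the ``*_mean``/``*_sd`` pairs), which is what
    gives the simulated congruency effects a known true reliability.

    Parameters
    ----------
    n_participants, n_blocks, trials_per_block
        Design size. ``trials_per_block`` must be even: each block holds equal
        numbers of congruent and incongruent trials in randomized order.
    it_baseline_mean, it_baseline_sd, mt_baseline_mean, mt_baseline_sd
        Between-participant baseline distributions (ms).
    it_congruency_mean, it_congruency_sd
        Trial-n incongruency effect on IT (ms, between-participant).
    it_prev_congruency_mean, it_prev_congruency_sd
        Trial n-1 incongruency effect on IT (ms).
    mt_congruency_mean, mt_congruency_sd
        Trial-n incongruency effect on MT (ms).
    mt_cIr_boost_mean, mt_cIr_boost_sd
        Extra MT on incongruent trials preceded by a congruent trial with a
        response repetition (ms).
    it_noise_sd, mt_noise_sd
        Within-participant trial noise (ms).
    partial_error_prob_*, overt_error_prob_*
        Per-trial probabilities by congruency condition.
    commitment_fraction_mean, commitment_fraction_sd
        On partial-error trials, the fraction of the movement initially headed
        toward the wrong target (unitless, in (0, 1)).
    correction_cost_ms
        MT cost of an in-flight correction at commitment fraction 1; the cost
        added on a partial-error trial is ``correction_cost_ms * fraction``.
    geometry, sampling_rate, onset_jitter_sd
        Trajectory synthesis parameters (``mode="trajectory"`` only).
    mode
        ``"summary"`` emits the trial table alone; ``"trajectory"`` also emits
        one raw trajectory per trial.
    seed
        Seed for all randomness; identical configs give byte-identical tables.
    """

    n_participants: int = 51
    n_blocks: int = 4
    trials_per_block: int = 48
    it_baseline_mean: float = 350.0
    it_baseline_sd: float = 50.0
    mt_baseline_mean: float = 300.0
    mt_baseline_sd: float = 60.0
    it_congruency_mean: float = 30.0
    it_congruency_sd: float = 36.0
    it_prev_congruency_mean: float = 15.0
    it_prev_congruency_sd: float = 20.0
    mt_congruency_mean: float = 56.0
    mt_congruency_sd: float = 28.0
    mt_cIr_boost_mean: float = 40.0
    mt_cIr_boost_sd: float = 25.0
    it_noise_sd: float = 60.0
    mt_noise_sd: float = 80.0
    partial_error_prob_incongruent: float = 0.15
    partial_error_prob_congruent: float = 0.03
    overt_error_prob_incongruent: float = 0.019
    overt_error_prob_congruent: float = 0.005
    commitment_fraction_mean: float = 0.30
    commitment_fraction_sd: float = 0.10
    correction_cost_ms: float = 100.0
    geometry: Geometry = field(default_factory=Geometry)
    sampling_rate: float = 100.0
    onset_jitter_sd: float = 0.5
    mode: Literal["summary", "trajectory"] = "summary"
    seed: int = 0

    _PROBS = (
        "partial_error_prob_incongruent",
        "partial_error_prob_congruent",
        "overt_error_prob_incongruent",
        "overt_error_prob_congruent",
    )
    _SDS = (
        "it_baseline_sd",
        "mt_baseline_sd",
        "it_congruency_sd",
        "it_prev_congruency_sd",
        "mt_congruency_sd",
        "mt_cIr_boost_sd",
        "it_noise_sd",
        "mt_noise_sd",
        "commitment_fraction_sd",
        "onset_jitter_sd",
    )

    def validate(self) -> None:
        for name in ("n_participants", "n_blocks", "trials_per_block"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name}: must be a positive count")
        if self.trials_per_block % 2 != 0 or self.trials_per_block < 2:
            raise ConfigError("trials_per_block: must be even and >= 2")
        for name in self._PROBS:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: probability {p} outside [0, 1]")
        for name in self._SDS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: SD must be >= 0")
        if not 0.0 < self.commitment_fraction_mean < 1.0:
            raise ConfigError("commitment_fraction_mean: must lie in (0, 1)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate: must be > 0")
        if self.mode not in ("summary", "trajectory"):
            raise ConfigError(f"mode: {self.mode!r} not one of 'summary', 'trajectory'")
        if isinstance(self.geometry, Geometry):
            self.geometry.validate()
        else:
            raise ConfigError("geometry: expected a Geometry instance")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        geo = d.pop("geometry", None)
        cfg = cls(**d)
        if geo is not None:
            cfg.geometry = Geometry(
                start=tuple(geo["start"]),
                left_target=tuple(geo["left_target"]),
                right_target=tuple(geo["right_target"]),
            )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(_load_mapping(path))


@dataclass
class FilterConfig:
    """The trial exclusion ladder.

    Rules apply in a fixed order: first trial of each block, overt errors,
    post-error trials, absolute RT bounds by age group, then a per-participant
    per-congruency 3 SD response-time rule recomputed on the survivors of the
    earlier stages. Each excluded trial is attributed to the first rule that
    catches it, keeping the exclusion log additive.
    """

    rt_min: float = 200.0
    rt_max_adult: float = 2500.0
    rt_max_child: float = 4000.0
    sd_cutoff: float = 3.0
    exclude_first_of_block: bool = True
    exclude_errors: bool = True
    exclude_post_error: bool = True

    def validate(self) -> None:
        if self.rt_min >= min(self.rt_max_adult, self.rt_max_child):
            raise ConfigError("rt_min: must be below both rt_max bounds")
        if self.sd_cutoff <= 0:
            raise ConfigError("sd_cutoff: must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        return cls.from_dict(_load_mapping(path))


@dataclass
class PipelineConfig:
    """Full pipeline run: exactly one of simulation / trial_csv is active."""

    output_dir: str | Path = "splitreach_out"
    simulation: SimulationConfig | None = None
    trial_csv: str | Path | None = None
    trajectory_csv: str | Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    measures: Sequence[str] = ("rt", "it", "mt")
    log_transform: bool = False
    n_permutations: int = 5000
    seed: int = 0
    score_types: Sequence[str] = ("difference", "congruent_component", "incongruent_component")
    min_trials: int = 2
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulation is None) == (self.trial_csv is None):
            raise ConfigError(
                "exactly one of 'simulation' and 'trial_csv' must be set"
            )
        if self.simulation is not None:
            self.simulation.validate()
        self.filter.validate()
        if self.n_permutations < 1:
            raise ConfigError("n_permutations: must be >= 1")

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
            "trial_csv": None if self.trial_csv is None else str(self.trial_csv),
            "trajectory_csv": None if self.trajectory_csv is None else str(self.trajectory_csv),
            "filter": self.filter.to_dict(),
            "measures": list(self.measures),
            "log_transform": self.log_transform,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "score_types": list(self.score_types),
            "min_trials": self.min_trials,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("filter") is not None:
            d["filter"] = FilterConfig.from_dict(d["filter"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(_load_mapping(path))


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return data
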