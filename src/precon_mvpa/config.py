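"""Configuration objects for simulation and analysis runs.

Two dataclasses are exposed: :class:`SimConfig` parameterizes the
synthetic-experiment generator and :class:`RunConfig` parameterizes the
analysis pipeline. Both validate eagerly on construction and can be
round-tripped through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

#: Default ROI sizes (voxels). OFC subregions are larger than HPC ones so
#: that the feature-selection steps (40 / 20) give several grid points.
DEFAULT_ROI_VOXELS = {
    "ofc_medial": 200,
    "ofc_lateral": 200,
    "hpc_anterior": 100,
    "hpc_posterior": 100,
}

#: Feature-selection step sizes per ROI family.
DEFAULT_FEATURE_STEPS = {
    "ofc_medial": 40,
    "ofc_lateral": 40,
    "hpc_anterior": 20,
    "hpc_posterior": 20,
}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic sensory-preconditioning experiment.

    Effect-size parameters (``similarity_slope``, ``value_amplitude``,
    ``reactivation_gain``, ``coupling_modulation``) are the planted ground
    truth that parameter-recovery tests check against. Setting all of them
    to zero yields a null experiment.
    """

    # --- cohort / design counts -------------------------------------
    n_subjects: int = 24
    n_cue_sets: int = 8
    n_control_pairs: int = 4
    n_precond_runs: int = 4          # analyzed runs (the odd first run is excluded upstream)
    n_cond_runs: int = 5
    n_probe_runs: int = 1
    cond_reps_per_run: int = 2       # each B/D cue, per conditioning run
    probe_reps: int = 4              # each cue, in the probe run
    n_recognition_old: int = 16
    n_recognition_recombined: int = 16

    # --- voxel grid / acquisition ------------------------------------
    n_voxels_per_roi: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROI_VOXELS))
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0

    # --- stimulus timing (seconds) -----------------------------------
    cue_duration_precond_s: float = 3.0
    pair_gap_s: float = 0.3
    cue_duration_cond_s: float = 1.5
    feedback_duration_s: float = 1.5
    iti_range_precond_s: tuple[float, float] = (3.0, 11.0)
    iti_range_cond_s: tuple[float, float] = (3.0, 7.0)

    # --- planted neural effects --------------------------------------
    similarity_slope: float = 0.1        # Fisher-z units per preconditioning run
    value_amplitude: float = 1.0         # along the shared value axis, value ROI only
    reactivation_gain: float = 0.3       # in [0, 1]; probe A/C blend of paired cue
    coupling_modulation: float = 0.5     # PPI interaction contrast (precond - cond)
    plant_conditioning_reactivation: bool = False
    value_roi: str = "ofc_medial"
    coupling_seed_roi: str = "ofc_medial"
    coupling_target_roi: str = "hpc_posterior"
    random_effects: bool = False         # subject-level variability of effect sizes
    random_effects_cv: float = 0.3       # coefficient of variation when enabled

    # --- noise model --------------------------------------------------
    signal_scale: float = 3.0            # multiplies unit-norm latent patterns
    noise_sd: float = 1.0
    ar1: float = 0.3

    # --- behavior -----------------------------------------------------
    learning_rate: float = 0.8
    asymptote_hi: float = 0.95
    asymptote_lo: float = 0.05
    rt_intercept_s: float = 0.9
    rt_slope_s: float = -0.05            # per preconditioning run
    rt_noise_sd_s: float = 0.08
    dprime_mean: float = 1.5
    dprime_sd: float = 0.8
    dprime_inference_coupling: float = 1.5
    nonresponse_rate: float = 0.02
    precond_catch_rate: float = 0.15     # mismatching second cue -> button press

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_cue_sets": self.n_cue_sets,
            "n_control_pairs": self.n_control_pairs,
            "n_precond_runs": self.n_precond_runs,
            "n_cond_runs": self.n_cond_runs,
            "n_probe_runs": self.n_probe_runs,
            "cond_reps_per_run": self.cond_reps_per_run,
            "probe_reps": self.probe_reps,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.ar1 < 1.0:
            raise ConfigError(f"ar1 must be in [0, 1), got {self.ar1}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.reactivation_gain <= 1.0:
            raise ConfigError(
                f"reactivation_gain must be in [0, 1], got {self.reactivation_gain}")
        if not self.n_voxels_per_roi:
            raise ConfigError("n_voxels_per_roi must not be empty")
        for roi, n in self.n_voxels_per_roi.items():
            if n < self.min_voxels_per_roi:
                raise ConfigError(
                    f"ROI {roi!r} has {n} voxels; the latent-pattern basis needs "
                    f"at least {self.min_voxels_per_roi}")
        for roi in (self.value_roi, self.coupling_seed_roi, self.coupling_target_roi):
            if roi not in self.n_voxels_per_roi:
                raise ConfigError(f"ROI {roi!r} not present in n_voxels_per_roi")
        if not 0.0 <= self.nonresponse_rate < 1.0:
            raise ConfigError("nonresponse_rate must be in [0, 1)")

    @property
    def n_basis_directions(self) -> int:
        # 4 cues + 2 association axes per set, one cue per control pair,
        # plus the shared value axis.
        return 6 * self.n_cue_sets + self.n_control_pairs + 1

    @property
    def min_voxels_per_roi(self) -> int:
        # +1 because the basis is built orthogonal to the constant vector.
        return self.n_basis_directions + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_voxels_per_roi"] = dict(self.n_voxels_per_roi)
        d["iti_range_precond_s"] = list(self.iti_range_precond_s)
        d["iti_range_cond_s"] = list(self.iti_range_cond_s)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("iti_range_precond_s", "iti_range_cond_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunConfig:
    """Parameters of an analysis run over a (synthetic or real) dataset."""

    dataset_dir: str | Path = "."
    output_dir: str | Path = "results"
    rois: Sequence[str] = field(default_factory=lambda: list(DEFAULT_ROI_VOXELS))
    feature_steps: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_STEPS))
    n_permutations: int = 10_000
    svm_cost: float = 1.0
    tail: str = "greater"                 # directed hypotheses are one-tailed
    use_tmaps: bool = True                # similarity/decoding on t-maps, not betas
    searchlight_radius_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        for roi, step in self.feature_steps.items():
            if step < 1:
                raise ConfigError(f"feature step for {roi!r} must be >= 1")
        if self.tail not in ("greater", "less", "two-sided"):
            raise ConfigError(f"unknown tail {self.tail!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dataset_dir"] = str(self.dataset_dir)
        d["output_dir"] = str(self.output_dir)
        d["rois"] = list(self.rois)
        d["feature_steps"] = dict(self.feature_steps)
        return d


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(payload)


def save_sim_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig(**payload)
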