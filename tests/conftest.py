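"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from precon_mvpa.config import RunConfig, SimConfig
from precon_mvpa.synthgen import simulate_dataset


def small_sim_config(**overrides) -> SimConfig:
    """A fast-to-simulate configuration used throughout the suite."""
    params = dict(
        n_subjects=3,
        n_cue_sets=4,
        n_control_pairs=2,
        n_voxels_per_roi={"ofc_medial": 64, "hpc_posterior": 48},
        coupling_seed_roi="ofc_medial",
        coupling_target_roi="hpc_posterior",
        value_roi="ofc_medial",
        n_cond_runs=3,
        cond_reps_per_run=2,
        probe_reps=2,
        seed=11,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return simulate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_run_cfg(tiny_cfg) -> RunConfig:
    return RunConfig(
        rois=list(tiny_cfg.n_voxels_per_roi),
        feature_steps={"ofc_medial": 20, "hpc_posterior": 16},
        n_permutations=100,
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
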