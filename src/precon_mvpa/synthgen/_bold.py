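"""BOLD synthesis: design convolution times latent patterns plus AR(1) noise."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from precon_mvpa.config import SimConfig
from precon_mvpa.glm import _convolve_conditions
from precon_mvpa.synthgen._patterns import LatentPatterns

_BASELINE = 100.0
_EVENT_AMPLITUDE = 0.5      # uniform spatial response to presses/outcomes
_NUISANCE_AMPLITUDE = 0.3
_AR_BURN_IN = 50


def ar1_noise(rng: np.random.Generator, n_volumes: int, n_voxels: int,
              sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    e = rng.standard_normal((n_volumes + _AR_BURN_IN, n_voxels)) * innov_sd
    x = lfilter([1.0], [1.0, -ar1], e, axis=0)
    return x[_AR_BURN_IN:]


def respiration_like_nuisance(rng: np.random.Generator, n_volumes: int,
                              tr_s: float) -> np.ndarray:
    """A slow, z-scored confound series standing in for a breathing trace."""
    t = np.arange(n_volumes) * tr_s
    period = rng.uniform(40.0, 80.0)
    phase = rng.uniform(0, 2 * np.pi)
    slow = np.sin(2 * np.pi * t / period + phase)
    walk = np.cumsum(rng.standard_normal(n_volumes))
    walk -= np.linspace(walk[0], walk[-1], n_volumes)
    series = slow + 0.3 * walk / max(walk.std(), 1e-12)
    return (series - series.mean()) / series.std()


def convolved_cue_regressors(
    events: pd.DataFrame, n_volumes: int, tr_s: float,
) -> tuple[dict[str, np.ndarray], dict[str, tuple]]:
    """HRF-convolved regressor per unique stimulus, plus its identity.

    Returns (regressors, identity) where identity maps the regressor
    name to (phase, role, 0-based cue index, run).
    """
    onsets: dict[str, list] = {}
    identity: dict[str, tuple] = {}
    cues = events[events["trial_type"] == "cue"]
    for _, row in cues.iterrows():
        role = row["cue_role"]
        if role == "E":
            idx = int(row["control_pair"])
        else:
            idx = int(row["cue_set"]) - 1
        name = f"{role}{idx}"
        onsets.setdefault(name, []).append(
            (float(row["onset"]), float(row["duration"])))
        identity[name] = (row["phase"], role, idx, int(row["run"]))
    regs = _convolve_conditions(onsets, n_volumes, tr_s)
    return regs, identity


def event_regressors(
    events: pd.DataFrame, n_volumes: int, tr_s: float,
) -> dict[str, np.ndarray]:
    """Convolved regressors for non-cue events (presses, outcomes)."""
    onsets: dict[str, list] = {}
    for _, row in events.iterrows():
        if row["trial_type"] == "cue":
            continue
        onsets.setdefault(row["trial_type"], []).append(
            (float(row["onset"]), float(row["duration"])))
    return _convolve_conditions(onsets, n_volumes, tr_s) if onsets else {}


def synthesize_run_bold(
    cfg: SimConfig,
    events: pd.DataFrame,
    n_volumes: int,
    latents: LatentPatterns,
    rng: np.random.Generator,
    nuisance: np.ndarray,
) -> np.ndarray:
    """(volumes x voxels) BOLD for one run in one ROI.

    Each stimulus contributes its convolved regressor times its latent
    pattern (scaled by ``signal_scale``); presses and outcomes add a
    spatially uniform response; the nuisance series leaks in with a
    small uniform weight; AR(1) noise and a constant baseline close it.
    """
    n_vox = cfg.n_voxels_per_roi[latents.roi]
    bold = np.full((n_volumes, n_vox), _BASELINE)
    regs, identity = convolved_cue_regressors(events, n_volumes, cfg.tr_s)
    for name, reg in regs.items():
        phase, role, idx, run = identity[name]
        pattern = latents.pattern_for_event(phase, role, idx, run)
        bold += np.outer(reg, cfg.signal_scale * pattern)
    for reg in event_regressors(events, n_volumes, cfg.tr_s).values():
        bold += _EVENT_AMPLITUDE * reg[:, None]
    bold += _NUISANCE_AMPLITUDE * nuisance[:, None]
    bold += ar1_noise(rng, n_volumes, n_vox, cfg.noise_sd, cfg.ar1)
    return bold
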