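"""Psychophysiological-interaction (PPI) connectivity.

Seed-to-target coupling change between psychological contexts
(preconditioned-cue vs. conditioned-cue trials) is estimated by a GLM
whose interaction columns multiply the seed BOLD series with each
HRF-convolved context regressor (BOLD-level, gPPI-style column
structure; no neural-level deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from precon_mvpa.behav_stats import StatResult, pearson_correlation
from precon_mvpa.glm import DesignMatrix, GlmError, _convolve_conditions, fit_glm
from precon_mvpa.ioconfig.volumes import RoiMask

__all__ = [
    "PpiEstimate",
    "seed_timecourse",
    "ppi_fit",
    "connectivity_behavior_correlation",
    "ConnError",
]

PRECONDITIONED_ROLES = ("A", "C")
CONDITIONED_ROLES = ("B", "D")


class ConnError(ValueError):
    pass


@dataclass
class PpiEstimate:
    """Interaction betas for the two psychological contexts (one subject)."""

    beta_precond: np.ndarray | float
    beta_cond: np.ndarray | float
    seed: str = ""
    target: str = ""

    @property
    def contrast(self):
        return self.beta_precond - self.beta_cond


def seed_timecourse(bold: np.ndarray, mask: RoiMask | None = None) -> np.ndarray:
    """Volume-wise mean over seed voxels, mean-centered.

    ``bold`` is either (volumes x voxels) over the seed ROI, or a 4-D
    array from which ``mask`` voxels are extracted.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 4:
        if mask is None:
            raise ConnError("a mask is required for 4-D input")
        bold = mask.extract(bold)
    if bold.ndim == 1:
        bold = bold[:, None]
    if bold.shape[1] == 0:
        raise ConnError("empty seed mask")
    series = bold.mean(axis=1)
    return series - series.mean()


def ppi_fit(
    seed_series: np.ndarray,
    events: pd.DataFrame,
    target_bold: np.ndarray,
    tr_s: float,
    nuisance: np.ndarray | None = None,
    seed_name: str = "",
    target_name: str = "",
) -> PpiEstimate:
    """Fit the PPI GLM for one subject/run.

    Columns: the two HRF-convolved psychological regressors, the raw
    seed series, one interaction column per context (seed x convolved
    context), any button-press regressors present in the events, the
    supplied nuisance columns, and a constant. Returns the interaction
    betas; the contrast is preconditioned minus conditioned.
    """
    seed = np.asarray(seed_series, dtype=float)
    target = np.asarray(target_bold, dtype=float)
    if target.ndim == 1:
        target = target[:, None]
    n_vol = target.shape[0]
    if seed.shape[0] != n_vol:
        raise ConnError("seed and target volume counts differ")
    seed = seed - seed.mean()
    if np.allclose(seed, 0.0):
        # degenerate seed: no physiological variance, so no interaction
        zeros = (0.0 if target.shape[1] == 1
                 else np.zeros(target.shape[1]))
        return PpiEstimate(beta_precond=zeros, beta_cond=zeros,
                           seed=seed_name, target=target_name)

    cues = events[events["trial_type"] == "cue"]
    onsets = {
        "psych_precond": [
            (float(r["onset"]), float(r["duration"]))
            for _, r in cues.iterrows() if r["cue_role"] in PRECONDITIONED_ROLES],
        "psych_cond": [
            (float(r["onset"]), float(r["duration"]))
            for _, r in cues.iterrows() if r["cue_role"] in CONDITIONED_ROLES],
    }
    for name, lst in onsets.items():
        if not lst:
            raise ConnError(f"no events for context {name!r}")
    for press in ("press_left", "press_right"):
        rows = events[events["trial_type"] == press]
        if len(rows):
            onsets[press] = [(float(r["onset"]), float(r["duration"]))
                             for _, r in rows.iterrows()]

    regs = _convolve_conditions(onsets, n_vol, tr_s)
    names = ["psych_precond", "psych_cond", "seed",
             "ppi_precond", "ppi_cond"]
    cols = [regs["psych_precond"], regs["psych_cond"], seed,
            seed * regs["psych_precond"], seed * regs["psych_cond"]]
    for press in ("press_left", "press_right"):
        if press in regs:
            names.append(press)
            cols.append(regs[press])
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != n_vol:
            nuis = nuis.T
        if nuis.shape[0] != n_vol:
            raise ConnError("nuisance rows must equal the volume count")
        for j in range(nuis.shape[1]):
            names.append(f"nuisance_{j}")
            cols.append(nuis[:, j])
    names.append("constant")
    cols.append(np.ones(n_vol))

    design = DesignMatrix(X=np.column_stack(cols), names=names,
                          condition_idx=[3, 4], tr_s=tr_s)
    try:
        est = fit_glm(target, design,
                      labels=pd.DataFrame({"condition": ["ppi_precond",
                                                         "ppi_cond"]}))
    except GlmError as exc:
        raise ConnError(str(exc)) from exc
    beta_pre, beta_cond = est.betas[0], est.betas[1]
    if beta_pre.size == 1:
        beta_pre, beta_cond = float(beta_pre[0]), float(beta_cond[0])
    return PpiEstimate(beta_precond=beta_pre, beta_cond=beta_cond,
                       seed=seed_name, target=target_name)


def connectivity_behavior_correlation(
    contrasts,
    behavior,
    tail: str = "two-sided",
) -> StatResult:
    """Across-subject Pearson correlation of PPI contrasts with behavior."""
    return pearson_correlation(contrasts, behavior, tail=tail,
                               name="connectivity_behavior")
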