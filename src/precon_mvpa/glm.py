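"""First-level GLM pattern estimation.

Condition regressors are boxcars convolved with a canonical double-gamma
hemodynamic response function on a fine microtime grid, sampled at volume
midpoints. Ordinary least squares yields per-condition beta maps and
t-maps (condition vs. implicit baseline) over ROI voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "canonical_hrf",
    "assign_conditions",
    "build_design",
    "cosine_drift",
    "fit_glm",
    "DesignMatrix",
    "PatternEstimates",
    "GlmError",
]

#: Microtime resolution (s) for regressor construction.
MICROTIME_DT = 0.1

# Canonical double-gamma parameters: response peak 6 s, undershoot peak
# 16 s, peak-to-undershoot ratio 6, both with unit dispersion.
_HRF_PEAK_DELAY = 6.0
_HRF_UNDERSHOOT_DELAY = 16.0
_HRF_RATIO = 6.0


class GlmError(ValueError):
    """Raised for invalid designs (rank deficiency, empty conditions...)."""


def canonical_hrf(dt: float = MICROTIME_DT, duration: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``[0, duration]``.

    The kernel is peak-normalized to 1. ``h(0) = 0`` and the late tail
    (12-20 s) is negative (post-stimulus undershoot).
    """
    if dt <= 0:
        raise GlmError(f"dt must be > 0, got {dt}")
    if duration < _HRF_PEAK_DELAY:
        raise GlmError(
            f"duration {duration} s is shorter than the response peak "
            f"({_HRF_PEAK_DELAY} s)")
    t = np.arange(0.0, duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=_HRF_PEAK_DELAY, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=_HRF_UNDERSHOOT_DELAY, scale=1.0)
    h = peak - undershoot / _HRF_RATIO
    return h / h.max()


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with named columns."""

    X: np.ndarray
    names: list[str]
    condition_idx: list[int]
    tr_s: float

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.names):
            raise GlmError("column count does not match name count")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    @property
    def condition_names(self) -> list[str]:
        return [self.names[i] for i in self.condition_idx]


@dataclass
class PatternEstimates:
    """Per-condition beta and t vectors over ROI voxels."""

    betas: np.ndarray            # (n_conditions, n_voxels)
    tvals: np.ndarray            # (n_conditions, n_voxels)
    df_resid: int
    labels: pd.DataFrame         # one row per condition; includes 'condition'
    roi: str = ""

    def patterns(self, use_tmaps: bool = True) -> np.ndarray:
        return self.tvals if use_tmaps else self.betas

    def select(self, **criteria) -> "PatternEstimates":
        """Subset conditions by label equality, e.g. ``cue_role="A"``."""
        mask = np.ones(len(self.labels), dtype=bool)
        for key, value in criteria.items():
            col = self.labels[key]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= col.isin(list(value)).to_numpy()
            else:
                mask &= (col == value).to_numpy()
        idx = np.flatnonzero(mask)
        return PatternEstimates(
            betas=self.betas[idx],
            tvals=self.tvals[idx],
            df_resid=self.df_resid,
            labels=self.labels.iloc[idx].reset_index(drop=True),
            roi=self.roi,
        )


def assign_conditions(events: pd.DataFrame, scheme: str = "by_role") -> pd.Series:
    """Derive the GLM condition name for each event row.

    ``by_role`` pools the cue sets into one regressor per cue role (the
    preconditioning/conditioning scheme: A, B, C, D, E). ``by_cue`` keeps
    one regressor per individual symbol (the probe scheme: A1..D8, E1..).
    Non-cue rows (outcome, press_left, press_right) keep their own name
    in both schemes.
    """
    if scheme not in ("by_role", "by_cue"):
        raise GlmError(f"unknown condition scheme {scheme!r}")
    names = []
    for _, row in events.iterrows():
        ttype = row.get("trial_type", "cue")
        if ttype != "cue":
            names.append(str(ttype))
        else:
            role = str(row["cue_role"])
            if scheme == "by_role" or pd.isna(row.get("cue_set")):
                names.append(role)
            else:
                names.append(f"{role}{int(row['cue_set'])}")
    return pd.Series(names, index=events.index, name="condition")


def _convolve_conditions(
    onsets_by_cond: dict[str, list[tuple[float, float]]],
    n_volumes: int,
    tr_s: float,
) -> dict[str, np.ndarray]:
    hrf = canonical_hrf(MICROTIME_DT)
    run_len_s = n_volumes * tr_s
    n_micro = int(np.ceil(run_len_s / MICROTIME_DT)) + 1
    # volume midpoints: volume k covers [k*TR, (k+1)*TR)
    sample_t = (np.arange(n_volumes) + 0.5) * tr_s
    sample_idx = np.round(sample_t / MICROTIME_DT).astype(int)

    out = {}
    for name, onsets in onsets_by_cond.items():
        box = np.zeros(n_micro)
        for onset, duration in onsets:
            if onset < 0 or onset > run_len_s:
                raise GlmError(
                    f"event at {onset} s lies outside the {run_len_s} s scan window")
            i0 = int(np.round(onset / MICROTIME_DT))
            i1 = int(np.round((onset + max(duration, MICROTIME_DT)) / MICROTIME_DT))
            box[i0:max(i1, i0 + 1)] = 1.0
        reg = np.convolve(box, hrf)[:n_micro] * MICROTIME_DT
        out[name] = reg[sample_idx]
    return out


def build_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    nuisance: np.ndarray | None = None,
    scheme: str = "by_role",
    highpass_s: float | None = None,
) -> DesignMatrix:
    """Build the first-level design for one run.

    Condition columns (HRF-convolved boxcars) come first in sorted name
    order, then nuisance columns (appended unmodified), an optional
    cosine drift set, and a constant column.
    """
    if n_volumes < 1:
        raise GlmError("n_volumes must be >= 1")
    cond = assign_conditions(events, scheme=scheme) if len(events) else pd.Series(dtype=str)

    onsets_by_cond: dict[str, list[tuple[float, float]]] = {}
    for i in range(len(events)):
        row = events.iloc[i]
        duration = float(row["duration"])
        if duration < 0:
            raise GlmError(f"negative duration at onset {row['onset']}")
        onsets_by_cond.setdefault(cond.iloc[i], []).append(
            (float(row["onset"]), duration))

    names = sorted(onsets_by_cond)
    regs = _convolve_conditions(onsets_by_cond, n_volumes, tr_s)
    columns = [regs[n] for n in names]
    for n in names:
        if not np.any(regs[n]):
            raise GlmError(f"condition {n!r} produces an all-zero column")
    condition_idx = list(range(len(names)))

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_volumes:
            raise GlmError("nuisance rows must equal the volume count")
        for j in range(nuisance.shape[1]):
            columns.append(nuisance[:, j])
            names.append(f"nuisance_{j}")

    if highpass_s is not None:
        drift = cosine_drift(n_volumes, tr_s, highpass_s)
        for j in range(drift.shape[1]):
            columns.append(drift[:, j])
            names.append(f"cosine_{j}")

    columns.append(np.ones(n_volumes))
    names.append("constant")
    X = np.column_stack(columns) if columns else np.ones((n_volumes, 1))
    return DesignMatrix(X=X, names=list(names), condition_idx=condition_idx, tr_s=tr_s)


def cosine_drift(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass basis (periods longer than ``cutoff_s``)."""
    order = int(np.floor(2 * n_volumes * tr_s / cutoff_s))
    t = np.arange(n_volumes)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, order + 1)]
    if not basis:
        return np.empty((n_volumes, 0))
    return np.column_stack(basis)


def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    labels: pd.DataFrame | None = None,
    roi: str = "",
) -> PatternEstimates:
    """Ordinary-least-squares fit; t-maps for each condition vs. baseline.

    ``bold`` is (volumes x voxels). Voxels where the residual standard
    error is exactly zero get t = 0 rather than an undefined ratio.
    """
    Y = np.asarray(bold, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise GlmError(
            f"BOLD has {Y.shape[0]} volumes but the design has {n} rows")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        culprits = _collinear_columns(X, design.names)
        raise GlmError(
            f"rank-deficient design (rank {rank} < {p} columns); "
            f"collinear columns involve: {culprits}")
    if rank >= n:
        raise GlmError("design has no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                      # (p, n_voxels)
    resid = Y - X @ beta
    df = n - rank
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df

    cond_idx = np.asarray(design.condition_idx, dtype=int)
    betas = beta[cond_idx]
    se = np.sqrt(np.outer(np.diag(xtx_inv)[cond_idx], sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, betas / se, 0.0)

    if labels is None:
        labels = pd.DataFrame({"condition": design.condition_names})
    else:
        labels = labels.reset_index(drop=True)
        if len(labels) != len(cond_idx):
            raise GlmError("labels must have one row per condition")
    return PatternEstimates(betas=betas, tvals=tvals, df_resid=df,
                            labels=labels, roi=roi)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns implicated in the rank deficiency (QR pivot heuristic)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[i] for i in np.flatnonzero(diag <= tol)]
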