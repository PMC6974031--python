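"""Latent voxel patterns with planted representational structure.

Each cue owns a direction in an orthonormal, voxel-mean-zero basis, so
Pearson correlations between latent patterns equal their coefficients
exactly. Cue-cue learning is planted by rotating both members of a pair
toward a shared association axis so that their correlation follows the
configured Fisher-z trajectory; outcome value adds a shared value axis
in the designated ROI; reactivation blends the paired cue's
end-of-preconditioning pattern into probe responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from precon_mvpa.config import SimConfig


@dataclass
class SubjectEffects:
    """Realized effect sizes for one subject (ground truth)."""

    similarity_slope: float
    value_amplitude: float
    reactivation_gain: float
    coupling_modulation: float
    dprime: float = np.nan


class LatentPatterns:
    """Noise-free cue patterns for one subject in one ROI."""

    def __init__(self, cfg: SimConfig, roi: str, rng: np.random.Generator,
                 effects: SubjectEffects):
        self.cfg = cfg
        self.roi = roi
        self.effects = effects
        n_vox = cfg.n_voxels_per_roi[roi]
        n_sets = cfg.n_cue_sets
        k = cfg.n_basis_directions

        # Orthonormal basis orthogonal to the constant vector: columns have
        # zero voxel mean and unit norm, so dot products are exact Pearson r.
        raw = rng.standard_normal((n_vox, k))
        m = np.column_stack([np.ones(n_vox), raw])
        q, _ = np.linalg.qr(m)
        basis = q[:, 1:k + 1]

        self._a = basis[:, 0:n_sets].T
        self._b = basis[:, n_sets:2 * n_sets].T
        self._c = basis[:, 2 * n_sets:3 * n_sets].T
        self._d = basis[:, 3 * n_sets:4 * n_sets].T
        self._m_ab = basis[:, 4 * n_sets:5 * n_sets].T
        self._m_cd = basis[:, 5 * n_sets:6 * n_sets].T
        self._e = basis[:, 6 * n_sets:6 * n_sets + cfg.n_control_pairs].T
        self.value_axis = basis[:, -1]

        self._value = (effects.value_amplitude
                       if roi == cfg.value_roi else 0.0)

    # -- preconditioning ------------------------------------------------
    def _mix(self, run: int) -> tuple[float, float]:
        """cos/sin weights so that corr(first, second) = tanh(z_run)."""
        z = self.effects.similarity_slope * (run - 1)
        rho = min(np.tanh(max(z, 0.0)), 1.0 - 1e-9)
        return float(np.sqrt(1.0 - rho)), float(np.sqrt(rho))

    def precond(self, role: str, cue_set: int | None, run: int) -> np.ndarray:
        if role == "E":
            return self._e[cue_set]
        cos_t, sin_t = self._mix(run)
        i = cue_set
        if role == "A":
            return cos_t * self._a[i] + sin_t * self._m_ab[i]
        if role == "B":
            return cos_t * self._b[i] + sin_t * self._m_ab[i]
        if role == "C":
            return cos_t * self._c[i] + sin_t * self._m_cd[i]
        if role == "D":
            return cos_t * self._d[i] + sin_t * self._m_cd[i]
        raise ValueError(f"unknown role {role!r}")

    # -- conditioning ---------------------------------------------------
    def conditioning(self, role: str, cue_set: int) -> np.ndarray:
        last = self.cfg.n_precond_runs
        base = self.precond(role, cue_set, last)
        if role == "B":
            pat = base + self._value * self.value_axis
            if self.cfg.plant_conditioning_reactivation:
                pat = pat + (self.effects.reactivation_gain
                             * self.precond("A", cue_set, last))
            return pat
        if role == "D":
            pat = base - self._value * self.value_axis
            if self.cfg.plant_conditioning_reactivation:
                pat = pat + (self.effects.reactivation_gain
                             * self.precond("C", cue_set, last))
            return pat
        raise ValueError(f"conditioning role must be B or D, got {role!r}")

    # -- probe ----------------------------------------------------------
    def probe(self, role: str, cue_set: int) -> np.ndarray:
        last = self.cfg.n_precond_runs
        g = self.effects.reactivation_gain
        if role in ("B", "D"):
            sign = 1.0 if role == "B" else -1.0
            return (self.precond(role, cue_set, last)
                    + sign * self._value * self.value_axis)
        if role == "A":
            return ((1 - g) * self.precond("A", cue_set, last)
                    + g * self.precond("B", cue_set, last)
                    + self._value * self.value_axis)
        if role == "C":
            return ((1 - g) * self.precond("C", cue_set, last)
                    - self._value * self.value_axis
                    + g * self.precond("D", cue_set, last))
        raise ValueError(f"unknown probe role {role!r}")

    def pattern_for_event(self, phase: str, role: str,
                          cue_set: int | None, run: int) -> np.ndarray:
        if phase == "preconditioning":
            return self.precond(role, cue_set, run)
        if phase == "conditioning":
            return self.conditioning(role, cue_set)
        if phase == "probe":
            return self.probe(role, cue_set)
        raise ValueError(f"unknown phase {phase!r}")
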