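"""Pattern-similarity analyses.

Tracks the acquisition of cue-cue associations as the Fisher-z paired
minus unpaired pattern correlation across preconditioning runs, tests
reactivation of earlier cue representations in later phases, and applies
the scan-day control subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from precon_mvpa.behav_stats import StatResult, group_t, tail_pvalue, StatsError
from precon_mvpa.glm import PatternEstimates

__all__ = [
    "z_similarity",
    "paired_contrast_trajectory",
    "linear_trend_test",
    "reactivation_contrast",
    "scanday_control_contrast",
    "scanday_corrected_contrast",
    "ReactivationResult",
    "RsaError",
]

#: Correlations are clipped to +/- (1 - _R_EPS) before atanh.
_R_EPS = 1e-7

#: Within-pair and between-pair role pairings (first cue, second cue).
PAIRED_ROLES = (("A", "B"), ("C", "D"))
UNPAIRED_ROLES = (("A", "D"), ("C", "B"))


class RsaError(ValueError):
    pass


@dataclass
class ReactivationResult:
    """Per-subject reactivation contrasts for one analysis variant."""

    values: np.ndarray
    variant: str                      # conditioning-BD | probe-AC | probe-AC-daycorrected
    roi: str = ""


def z_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Fisher-z transformed Pearson correlation between two voxel vectors.

    Perfectly (anti)correlated inputs are clipped to ``+/-atanh(1-1e-7)``
    with a warning rather than returning infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RsaError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise RsaError("need at least 3 voxels")
    if x.std() == 0 or y.std() == 0:
        raise RsaError("zero-variance input pattern")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1 - _R_EPS:
        warnings.warn("correlation at unit magnitude; Fisher z clipped",
                      RuntimeWarning, stacklevel=2)
        r = np.sign(r) * (1 - _R_EPS)
    return float(np.arctanh(r))


def _role_patterns(
    estimates: PatternEstimates,
    use_tmaps: bool,
) -> dict[tuple[str, object], np.ndarray]:
    """Map (cue_role, cue_set) -> pattern. cue_set is None when pooled."""
    pats = estimates.patterns(use_tmaps)
    out: dict[tuple[str, object], np.ndarray] = {}
    labels = estimates.labels
    for i in range(len(labels)):
        role = labels.iloc[i].get("cue_role")
        if role is None or (isinstance(role, float) and np.isnan(role)):
            continue
        cs = labels.iloc[i].get("cue_set")
        key = (str(role), None if cs is None or pd.isna(cs) else int(cs))
        out[key] = pats[i]
    return out


def _mean_pair_z(
    patterns: Mapping[tuple[str, object], np.ndarray],
    role_pairs: Sequence[tuple[str, str]],
) -> float:
    """Mean Fisher-z over role pairs, per cue set when sets are present.

    Fisher-z is applied per pair before averaging (z-then-average).
    """
    zs = []
    sets = sorted({k[1] for k in patterns if k[1] is not None},
                  key=lambda s: (s is None, s))
    keys = sets if sets else [None]
    for first, second in role_pairs:
        for cs in keys:
            a = patterns.get((first, cs))
            b = patterns.get((second, cs))
            if a is None or b is None:
                raise RsaError(
                    f"missing condition for role pair ({first},{second}) set {cs}")
            zs.append(z_similarity(a, b))
    return float(np.mean(zs))


def paired_contrast_trajectory(
    estimates_per_run: Sequence[PatternEstimates],
    use_tmaps: bool = True,
    paired: Sequence[tuple[str, str]] = PAIRED_ROLES,
    unpaired: Sequence[tuple[str, str]] = UNPAIRED_ROLES,
) -> pd.DataFrame:
    """Per-run paired vs unpaired similarity for a single subject and ROI.

    Returns a table with ``run`` (1-based), ``z_within``, ``z_between``
    and ``delta = z_within - z_between``. Works with role-pooled
    estimates (one pattern per role) as well as per-cue-set estimates
    (z averaged over sets).
    """
    if len(estimates_per_run) < 1:
        raise RsaError("need at least one run of estimates")
    rows = []
    for run_idx, est in enumerate(estimates_per_run, start=1):
        pats = _role_patterns(est, use_tmaps)
        zw = _mean_pair_z(pats, paired)
        zb = _mean_pair_z(pats, unpaired)
        rows.append({"run": run_idx, "z_within": zw, "z_between": zb,
                     "delta": zw - zb, "roi": est.roi})
    return pd.DataFrame(rows)


def linear_trend_test(
    values: np.ndarray | pd.DataFrame,
    tail: str = "greater",
) -> tuple[np.ndarray, StatResult]:
    """Per-subject linear trend across runs plus a group-level t-test.

    ``values`` is (subjects x runs) or a long table with ``subject``,
    ``run`` and ``delta`` columns. The slope is the least-squares
    regression coefficient of the values on the centered run index; the
    group test is a one-sample t of the slopes against zero. If every
    subject has an identical slope the t statistic is reported as
    +/-inf with a degenerate p-value.
    """
    if isinstance(values, pd.DataFrame):
        wide = values.pivot(index="subject", columns="run", values="delta")
        if wide.isna().any().any():
            raise RsaError("missing run values for some subject")
        mat = wide.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2 or mat.shape[0] < 2:
        raise RsaError("need >= 2 runs and >= 2 subjects")
    runs = np.arange(1, mat.shape[1] + 1, dtype=float)
    x = runs - runs.mean()
    if np.all(x == 0):
        raise RsaError("constant run index")
    slopes = mat @ x / (x @ x)

    if slopes.std(ddof=1) == 0:
        t = np.inf * np.sign(slopes.mean()) if slopes.mean() != 0 else 0.0
        df = slopes.size - 1
        p = tail_pvalue(t, df, tail) if np.isfinite(t) else (
            np.finfo(float).tiny
            if (tail == "two-sided"
                or (tail == "greater") == (t > 0))
            else 1.0)
        result = StatResult(name="linear_trend", statistic=float(t),
                            df1=df, p=float(p), tail=tail)
    else:
        result = group_t(slopes, 0.0, tail=tail, name="linear_trend")
    return slopes, result


def _role_template(
    estimates: PatternEstimates, role: str, use_tmaps: bool,
) -> np.ndarray:
    sub = estimates.select(cue_role=role)
    if len(sub.labels) == 0:
        raise RsaError(f"no conditions with cue_role {role!r}")
    return sub.patterns(use_tmaps).mean(axis=0)


def reactivation_contrast(
    template: PatternEstimates,
    precond_first: PatternEstimates,
    precond_last: PatternEstimates,
    roles: Sequence[str],
    use_tmaps: bool = True,
    variant: str = "",
    role_map: Mapping[str, str] | None = None,
) -> float:
    """Template-pattern similarity shift from first to last run (one subject).

    For each role, the template pattern (conditions with that role,
    averaged) is correlated with the same-role pattern in the last and
    first preconditioning runs; the result is the mean over roles of
    ``z(template, last) - z(template, first)``. ``role_map`` redirects
    each template role to a different preconditioning role (used by the
    scan-day control). Antisymmetric under swapping first/last inputs.
    """
    n_vox = template.patterns(use_tmaps).shape[1]
    for est in (precond_first, precond_last):
        if est.patterns(use_tmaps).shape[1] != n_vox:
            raise RsaError("voxel sets differ between phases")
    role_map = dict(role_map or {})
    diffs = []
    for role in roles:
        target_role = role_map.get(role, role)
        tpl = _role_template(template, role, use_tmaps)
        first = _role_template(precond_first, target_role, use_tmaps)
        last = _role_template(precond_last, target_role, use_tmaps)
        diffs.append(z_similarity(tpl, last) - z_similarity(tpl, first))
    return float(np.mean(diffs))


def scanday_control_contrast(
    template: PatternEstimates,
    precond_first: PatternEstimates,
    precond_last: PatternEstimates,
    roles: Sequence[str],
    control_map: Mapping[str, str],
    use_tmaps: bool = True,
) -> float:
    """First/last contrast computed on unrelated cue pairs (one subject).

    ``control_map`` sends each template role to a preconditioning role it
    was never paired with (e.g. A -> C). Overlapping roles are rejected.
    """
    for role, ctrl in control_map.items():
        if role == ctrl:
            raise RsaError(f"control role for {role!r} overlaps the target")
    return reactivation_contrast(
        template, precond_first, precond_last, roles,
        use_tmaps=use_tmaps, role_map=control_map)


def scanday_corrected_contrast(
    target_values: np.ndarray,
    control_values: np.ndarray,
) -> np.ndarray:
    """Subtract per-subject scan-day control contrasts from target contrasts."""
    t = np.asarray(target_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.shape != c.shape:
        raise RsaError("target and control value arrays must align")
    return t - c
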