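"""Behavioral summaries and shared group-level statistics.

Implements the statistical machinery used throughout the pipeline:
repeated-measures ANOVA with Greenhouse-Geisser correction, one-sample /
paired t-tests with configurable tails, Pearson correlations,
signal-detection d' with log-linear correction, behavioral learning
curves, and the performance-based subject exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

__all__ = [
    "BehaviorTable",
    "StatResult",
    "prediction_curves",
    "rm_anova",
    "dprime",
    "group_t",
    "pearson_correlation",
    "exclusion_filter",
    "tail_pvalue",
]


class StatsError(ValueError):
    """Raised on degenerate statistical input (zero variance, missing cells)."""


@dataclass
class StatResult:
    """A single test statistic with degrees of freedom and p-value.

    For repeated-measures F-tests, ``df1``/``df2`` are the (possibly
    fractional) Greenhouse-Geisser-corrected degrees of freedom and
    ``epsilon`` holds the sphericity estimate; for t-tests ``df2`` is None.
    """

    name: str
    statistic: float
    df1: float
    p: float
    tail: str = "two-sided"
    df2: float | None = None
    epsilon: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name, "statistic": self.statistic, "df1": self.df1,
            "df2": self.df2, "epsilon": self.epsilon, "p": self.p,
            "tail": self.tail,
        }


@dataclass
class BehaviorTable:
    """Trial-level behavioral data for one cohort.

    ``conditioning`` / ``probe`` hold one row per responded-to cue
    presentation (subject, run, cue_role, cue_set, repetition, response,
    response_time); ``precond_rt`` holds per subject x run mean response
    times from the pair-mismatch task; ``recognition`` holds per-subject
    old/recombined judgment counts.
    """

    conditioning: pd.DataFrame
    probe: pd.DataFrame
    precond_rt: pd.DataFrame
    recognition: pd.DataFrame
    #: optional trial-level preconditioning table (catch flags + RTs)
    precond_trials: pd.DataFrame | None = None


def tail_pvalue(stat: float, df: float, tail: str) -> float:
    """p-value of a t statistic under the requested tail."""
    if tail == "two-sided":
        return float(2 * stats.t.sf(abs(stat), df))
    if tail == "greater":
        return float(stats.t.sf(stat, df))
    if tail == "less":
        return float(stats.t.cdf(stat, df))
    raise StatsError(f"unknown tail {tail!r}")


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------

def prediction_curves(events: pd.DataFrame) -> pd.DataFrame:
    """Percent reward-predicted (and mean RT) per cue role x repetition.

    Expects trial rows with ``cue_role``, ``response`` in {plus, minus,
    none} and optional ``response_time``/``subject``/``cue_set`` columns.
    Non-response trials are dropped from the denominator. Repetition is
    taken from a ``repetition`` column when present, otherwise derived
    from presentation order per individual cue.
    """
    df = events.copy()
    if "trial_type" in df.columns:
        df = df[df["trial_type"] == "cue"]
    if df.empty:
        raise StatsError("no cue trials in the event table")
    if "repetition" not in df.columns:
        keys = [c for c in ("subject", "cue_role", "cue_set") if c in df.columns]
        order = [c for c in ("run", "onset") if c in df.columns]
        df = df.sort_values(order) if order else df
        df["repetition"] = df.groupby(keys).cumcount() + 1

    df = df[df["response"].isin(["plus", "minus"])]
    if df.empty:
        raise StatsError("all trials are non-response trials")
    keys = [c for c in ("subject", "cue_role", "repetition") if c in df.columns]
    grouped = df.groupby(keys)
    out = grouped.agg(
        pct_reward_predicted=("response", lambda s: 100.0 * np.mean(s == "plus")),
        mean_rt=("response_time", "mean"),
        n=("response", "size"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the complement of the constant vector."""
    return null_space(np.ones((1, k)))


def _effect_f(scores: np.ndarray, name: str) -> StatResult:
    """Univariate RM F-test from orthonormalized contrast scores (n x q)."""
    n, q = scores.shape
    if n < 2:
        raise StatsError("need at least 2 subjects")
    mean = scores.mean(axis=0)
    ss_effect = n * float(mean @ mean)
    centered = scores - mean
    ss_error = float((centered ** 2).sum())
    df1, df2 = q, q * (n - 1)
    if ss_error <= 0:
        raise StatsError(f"zero error variance for effect {name!r}")
    F = (ss_effect / df1) / (ss_error / df2)

    cov = centered.T @ centered / (n - 1)
    tr = np.trace(cov)
    tr2 = np.trace(cov @ cov)
    eps = 1.0 if q == 1 else float(tr ** 2 / (q * tr2))
    eps = min(max(eps, 1.0 / q), 1.0)
    p = float(stats.f.sf(F, eps * df1, eps * df2))
    return StatResult(name=name, statistic=float(F), df1=eps * df1,
                      df2=eps * df2, epsilon=eps, p=p, tail="two-sided")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
) -> list[StatResult]:
    """Repeated-measures ANOVA for one or two within-subject factors.

    The design must be complete and balanced (one observation per
    subject x cell; replicate observations are averaged first). Returns
    main effects and, for two factors, their interaction; degrees of
    freedom and p-values carry the Greenhouse-Geisser correction.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise StatsError("rm_anova supports 1 or 2 within factors")
    agg = data.groupby([subject] + within, sort=True)[dv].mean()
    wide = agg.unstack(within)
    if wide.isna().any().any():
        raise StatsError("incomplete design: missing subject x cell combinations")
    Y = wide.to_numpy(dtype=float)

    if len(within) == 1:
        k = wide.shape[1]
        M = _orthonormal_contrasts(k)
        return [_effect_f(Y @ M, within[0])]

    levels_a = wide.columns.get_level_values(0).unique()
    levels_b = wide.columns.get_level_values(1).unique()
    ka, kb = len(levels_a), len(levels_b)
    # columns of `wide` are ordered (a1,b1),(a1,b2),... thanks to sort=True
    Ma, Mb = _orthonormal_contrasts(ka), _orthonormal_contrasts(kb)
    ones_a = np.ones((ka, 1)) / np.sqrt(ka)
    ones_b = np.ones((kb, 1)) / np.sqrt(kb)
    results = [
        _effect_f(Y @ np.kron(Ma, ones_b), within[0]),
        _effect_f(Y @ np.kron(ones_a, Mb), within[1]),
        _effect_f(Y @ np.kron(Ma, Mb), f"{within[0]}:{within[1]}"),
    ]
    return results


# ---------------------------------------------------------------------------
# signal detection, t-tests, correlations
# ---------------------------------------------------------------------------

def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """d' with the log-linear correction applied unconditionally.

    0.5 is added to each cell and 1 to each denominator, keeping the
    statistic finite even for perfect or floor performance.
    """
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise StatsError("counts must be nonnegative")
    if hits + misses == 0 or false_alarms + correct_rejections == 0:
        raise StatsError("need at least one old and one recombined trial")
    hit_rate = (hits + 0.5) / (hits + misses + 1.0)
    fa_rate = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def group_t(
    values: Sequence[float],
    mu0: float = 0.0,
    tail: str = "two-sided",
    paired_with: Sequence[float] | None = None,
    name: str = "t",
) -> StatResult:
    """One-sample t-test of ``values`` against ``mu0``, or a paired test.

    In paired mode the test is a one-sample t on elementwise differences
    ``values - paired_with`` against ``mu0``.
    """
    x = np.asarray(values, dtype=float)
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise StatsError("paired samples must have equal length")
        x = x - y
    if x.size < 2:
        raise StatsError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance sample")
    n = x.size
    t = float((x.mean() - mu0) / (sd / np.sqrt(n)))
    return StatResult(name=name, statistic=t, df1=n - 1,
                      p=tail_pvalue(t, n - 1, tail), tail=tail)


def pearson_correlation(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two-sided",
    name: str = "r",
) -> StatResult:
    """Pearson correlation with a t-based p-value under the given tail."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt((n - 2) / (1 - r_ ** 2))
    return StatResult(name=name, statistic=r, df1=n - 2,
                      p=tail_pvalue(t, n - 2, tail), tail=tail)


def exclusion_filter(
    behavior: BehaviorTable,
    alpha: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Retain subjects whose final-run conditioning accuracy beats chance.

    Per subject, a one-tailed binomial test of correct predictions
    (plus for reward cues, minus for nonreward cues) against 0.5 in the
    last conditioning run; subjects with p < ``alpha`` are retained.
    Non-response trials do not count toward the denominator.
    """
    cond = behavior.conditioning
    if cond.empty:
        raise StatsError("no conditioning trials")
    last_run = cond["run"].max()
    final = cond[cond["run"] == last_run]
    rows = []
    retained = []
    for subj, grp in final.groupby("subject"):
        resp = grp[grp["response"].isin(["plus", "minus"])]
        n = len(resp)
        if n == 0:
            raise StatsError(f"subject {subj!r} has no last-run responses")
        correct = int((
            ((resp["cue_role"] == "B") & (resp["response"] == "plus"))
            | ((resp["cue_role"] == "D") & (resp["response"] == "minus"))
        ).sum())
        p = stats.binomtest(correct, n, 0.5, alternative="greater").pvalue
        keep = p < alpha
        rows.append({"subject": subj, "n_trials": n, "n_correct": correct,
                     "p": float(p), "retained": bool(keep)})
        if keep:
            retained.append(subj)
    return retained, pd.DataFrame(rows)
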