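"""Recompute published summary statistics from the per-panel source data.

The study's supplementary workbook ships the per-subject numbers behind
each figure panel, one sheet per panel. This module exposes one function
per recomputed statistic; each takes plain arrays/frames so the caller
controls how the sheets are parsed, plus :func:`recompute_all`, which
applies a best-effort parse of the workbook layout (first column =
subject when labeled, remaining columns = conditions in panel order).

The workbook is NOT distributed with this package; pass its path
explicitly (``data/s1_data.xlsx`` by convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from precon_mvpa import behav_stats, rsa

__all__ = [
    "load_workbook",
    "precond_rt_trend_t",
    "conditioning_cue_effect_f",
    "probe_paired_t",
    "dprime_inference_r",
    "similarity_trend_t",
    "decoding_vs_chance_t",
    "connectivity_rt_r",
    "recompute_all",
]


def load_workbook(path: str | Path) -> dict[str, pd.DataFrame]:
    """Load every sheet of the supplementary workbook into data frames."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary workbook not found at {path}; download the "
            "study's S1 Data spreadsheet and place it there")
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    return {str(k).strip().lower(): v for k, v in sheets.items()}


def _numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Drop non-numeric columns (subject labels, annotations)."""
    num = df.apply(pd.to_numeric, errors="coerce")
    num = num.dropna(axis=1, how="all").dropna(axis=0, how="all")
    return num


def precond_rt_trend_t(values: np.ndarray) -> float:
    """t of the per-subject linear RT trend across runs (subjects x runs)."""
    _, result = rsa.linear_trend_test(np.asarray(values, float),
                                      tail="two-sided")
    return result.statistic


def conditioning_cue_effect_f(long: pd.DataFrame) -> float:
    """Main effect of cue from the cue x repetition RM-ANOVA.

    ``long`` needs columns subject, cue_role, repetition and value.
    """
    results = behav_stats.rm_anova(long, "value",
                                   within=["cue_role", "repetition"])
    return results[0].statistic


def probe_paired_t(first: np.ndarray, second: np.ndarray) -> float:
    """Paired t between two per-subject response columns."""
    return behav_stats.group_t(first, paired_with=second,
                               tail="two-sided").statistic


def dprime_inference_r(dprime: np.ndarray, a_minus_c: np.ndarray) -> float:
    return behav_stats.pearson_correlation(dprime, a_minus_c).statistic


def similarity_trend_t(values: np.ndarray) -> float:
    """Group t of per-subject similarity slopes (subjects x runs)."""
    _, result = rsa.linear_trend_test(np.asarray(values, float),
                                      tail="greater")
    return result.statistic


def decoding_vs_chance_t(accuracy: np.ndarray, chance: np.ndarray) -> float:
    diff = np.asarray(accuracy, float) - np.asarray(chance, float)
    return behav_stats.group_t(diff, 0.0, tail="greater").statistic


def connectivity_rt_r(contrast: np.ndarray, rt: np.ndarray) -> float:
    return behav_stats.pearson_correlation(contrast, rt).statistic


def _cue_by_time_long(sheet: pd.DataFrame) -> pd.DataFrame:
    """Reshape a per-subject cue-by-repetition sheet into long format.

    Assumes the first half of the numeric columns belongs to the reward
    cue and the second half to the nonreward cue, repetitions in order.
    """
    num = _numeric(sheet)
    k = num.shape[1] // 2
    rows = []
    for s, (_, row) in enumerate(num.iterrows()):
        vals = row.to_numpy()
        for rep in range(k):
            rows.append({"subject": s, "cue_role": "B", "repetition": rep + 1,
                         "value": vals[rep]})
            rows.append({"subject": s, "cue_role": "D", "repetition": rep + 1,
                         "value": vals[k + rep]})
    return pd.DataFrame(rows)


def recompute_all(path: str | Path) -> dict[str, float]:
    """Recompute every statistic the acceptance targets track.

    Sheet-name matching is case-insensitive and keyed on the figure
    panel labels (2a, 2b, 2d, 2f, 3c, 4b, 4c, 6d).
    """
    sheets = load_workbook(path)

    def sheet(tag: str) -> pd.DataFrame:
        for name, df in sheets.items():
            if tag in name:
                return df
        raise KeyError(f"no sheet matching {tag!r} in the workbook")

    out: dict[str, float] = {}
    out["t1"] = precond_rt_trend_t(_numeric(sheet("2a")).to_numpy())
    out["t2"] = conditioning_cue_effect_f(_cue_by_time_long(sheet("2b")))
    probe = _numeric(sheet("2d"))
    # panel order: A, B, C, D response percentages
    cols = probe.to_numpy().T
    out["t3"] = probe_paired_t(cols[1], cols[3])     # B vs D
    out["t4"] = probe_paired_t(cols[0], cols[2])     # A vs C
    fig2f = _numeric(sheet("2f")).to_numpy().T
    out["t5"] = dprime_inference_r(fig2f[0], fig2f[1])
    out["t6"] = similarity_trend_t(_numeric(sheet("3c")).to_numpy())
    fig4b = _numeric(sheet("4b")).to_numpy().T
    out["t7"] = decoding_vs_chance_t(fig4b[0], fig4b[1])
    fig4c = _numeric(sheet("4c")).to_numpy().T
    out["t8"] = decoding_vs_chance_t(fig4c[0], fig4c[1])
    fig6d = _numeric(sheet("6d")).to_numpy().T
    out["t9"] = connectivity_rt_r(fig6d[0], fig6d[1])
    return out
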