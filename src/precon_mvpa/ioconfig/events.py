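"""BIDS-style event tables.

Events live in tab-separated files with one row per stimulus/response
event. Required columns: ``onset``, ``duration``, ``trial_type``. Cue
rows additionally carry ``phase``, ``run``, ``cue_role`` (A/B/C/D/E),
``cue_set`` (1..8, empty for E cues), ``position_in_pair`` (first/second,
preconditioning only), ``outcome``, ``response`` and ``response_time``
(empty cell when missing, never 0). Extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_events", "write_events", "validate_events", "EventValidationError"]

REQUIRED_COLUMNS = ("onset", "duration", "trial_type")

CUE_ROLES = {"A", "B", "C", "D", "E"}
PHASES = {"preconditioning", "conditioning", "probe", "recognition"}


class EventValidationError(ValueError):
    pass


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table; returns the (dtype-normalized) table.

    Checks: required columns, numeric onset/duration, strictly
    increasing onsets within each run, positive cue durations,
    E cues without a cue_set, conditioning cues limited to roles B/D.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise EventValidationError(f"missing required column {col!r}")
    df = df.copy()
    for col in ("onset", "duration", "response_time"):
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise EventValidationError(f"malformed numbers in {col!r}: {exc}")
    if "cue_set" in df.columns:
        df["cue_set"] = pd.to_numeric(df["cue_set"], errors="raise").astype("Int64")

    group_cols = [c for c in ("subject", "phase", "run") if c in df.columns]
    groups = df.groupby(group_cols, dropna=False) if group_cols else [(None, df)]
    for key, grp in groups:
        onsets = grp["onset"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise EventValidationError(
                f"onsets not strictly increasing within run {key!r}")
        if np.any(onsets < 0):
            raise EventValidationError(f"negative onset in run {key!r}")

    cues = df[df["trial_type"] == "cue"] if "trial_type" in df.columns else df
    if len(cues):
        if (cues["duration"].to_numpy(dtype=float) <= 0).any():
            raise EventValidationError("cue durations must be > 0")
        if "cue_role" in cues.columns:
            bad = set(cues["cue_role"].dropna()) - CUE_ROLES
            if bad:
                raise EventValidationError(f"unknown cue roles: {sorted(bad)}")
            if "cue_set" in cues.columns:
                e_with_set = cues[(cues["cue_role"] == "E")
                                  & cues["cue_set"].notna()]
                if len(e_with_set):
                    raise EventValidationError("E cues must not carry a cue_set")
        if "phase" in cues.columns and "cue_role" in cues.columns:
            cond = cues[cues["phase"] == "conditioning"]
            bad_roles = set(cond["cue_role"].dropna()) - {"B", "D"}
            if bad_roles:
                raise EventValidationError(
                    f"conditioning cues must be B or D, got {sorted(bad_roles)}")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a BIDS-style events TSV."""
    df = pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=True)
    return validate_events(df)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    """Write an events TSV (missing values as empty cells)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")
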