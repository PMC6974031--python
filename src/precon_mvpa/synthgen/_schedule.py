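"""Trial schedules: event tables for each run of each phase."""

from __future__ import annotations

import numpy as np
import pandas as pd

from precon_mvpa.config import SimConfig

#: extra scan time (s) after the last event, to catch the HRF tail
_RUN_PADDING_S = 14.0
_RUN_LEADIN_S = 6.0


def _n_volumes(t_end: float, tr_s: float) -> int:
    return int(np.ceil((t_end + _RUN_PADDING_S) / tr_s))


def precond_run_events(
    cfg: SimConfig, rng: np.random.Generator, subject: int, run: int,
    precond_trials: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """One preconditioning run: sequential cue pairs plus catch responses.

    Each trial shows the pair's first cue then its second, 3 s each with
    a 300 ms gap; catch trials (mismatching second symbol) carry a
    button response whose RT comes from the behavior table.
    """
    pairs = ([("A", "B", i) for i in range(1, cfg.n_cue_sets + 1)]
             + [("C", "D", i) for i in range(1, cfg.n_cue_sets + 1)]
             + [("E", "E", None)] * cfg.n_control_pairs)
    control_ids = iter(range(cfg.n_control_pairs))
    pairs = [(f, s, cs, next(control_ids) if f == "E" else None)
             for f, s, cs in pairs]
    order = rng.permutation(len(pairs))

    beh = precond_trials[(precond_trials["subject"] == subject)
                         & (precond_trials["run"] == run)]
    beh = beh.sort_values("trial").reset_index(drop=True)

    rows = []
    t = _RUN_LEADIN_S
    dur = cfg.cue_duration_precond_s
    for trial_idx, pair_idx in enumerate(order):
        first, second, cue_set, control_id = pairs[pair_idx]
        is_catch = bool(beh.iloc[trial_idx]["is_catch"]) if trial_idx < len(beh) else False
        rt = beh.iloc[trial_idx]["response_time"] if trial_idx < len(beh) else np.nan
        base = {
            "phase": "preconditioning", "run": run, "subject": subject,
            "trial_type": "cue", "outcome": "none",
        }
        rows.append({**base, "onset": t, "duration": dur, "cue_role": first,
                     "cue_set": cue_set, "control_pair": control_id,
                     "position_in_pair": "first",
                     "response": "none", "response_time": np.nan})
        t2 = t + dur + cfg.pair_gap_s
        rows.append({**base, "onset": t2, "duration": dur, "cue_role": second,
                     "cue_set": cue_set, "control_pair": control_id,
                     "position_in_pair": "second",
                     "response": "pair-different" if is_catch else "none",
                     "response_time": rt if is_catch else np.nan})
        t = t2 + dur + rng.uniform(*cfg.iti_range_precond_s)
    return pd.DataFrame(rows), _n_volumes(t, cfg.tr_s)


def _prediction_trial_rows(
    cfg: SimConfig, rng: np.random.Generator, subject: int, run: int,
    phase: str, beh_rows: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Shared builder for conditioning and probe runs.

    ``beh_rows`` supplies one row per (cue_role, cue_set, repetition)
    trial with the simulated response and RT; trials are shuffled into a
    random order and given onsets. Outcomes are modeled as zero-duration
    events at cue offset (conditioning only, responded trials only).
    """
    beh = beh_rows.sample(frac=1.0, random_state=rng.integers(2 ** 31)
                          ).reset_index(drop=True)
    rows = []
    t = _RUN_LEADIN_S
    dur = cfg.cue_duration_cond_s
    for _, trial in beh.iterrows():
        role = trial["cue_role"]
        outcome = "none"
        if phase == "conditioning":
            outcome = "$1" if role == "B" else "$0"
        responded = trial["response"] in ("plus", "minus")
        rows.append({
            "phase": phase, "run": run, "subject": subject,
            "trial_type": "cue", "onset": t, "duration": dur,
            "cue_role": role, "cue_set": trial["cue_set"],
            "control_pair": None, "position_in_pair": None,
            "outcome": outcome,
            "response": trial["response"],
            "response_time": trial["response_time"] if responded else np.nan,
        })
        if responded:
            side = "press_left" if rng.random() < 0.5 else "press_right"
            rows.append({
                "phase": phase, "run": run, "subject": subject,
                "trial_type": side,
                "onset": t + float(trial["response_time"]),
                "duration": 0.0, "cue_role": None, "cue_set": None,
                "control_pair": None, "position_in_pair": None,
                "outcome": "none", "response": "none", "response_time": np.nan,
            })
            if phase == "conditioning":
                rows.append({
                    "phase": phase, "run": run, "subject": subject,
                    "trial_type": "outcome", "onset": t + dur,
                    "duration": 0.0, "cue_role": None, "cue_set": None,
                    "control_pair": None, "position_in_pair": None,
                    "outcome": outcome, "response": "none",
                    "response_time": np.nan,
                })
        t += dur + cfg.feedback_duration_s + rng.uniform(*cfg.iti_range_cond_s)
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    return df, _n_volumes(t, cfg.tr_s)


def cond_run_events(
    cfg: SimConfig, rng: np.random.Generator, subject: int, run: int,
    conditioning: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    beh = conditioning[(conditioning["subject"] == subject)
                       & (conditioning["run"] == run)]
    return _prediction_trial_rows(cfg, rng, subject, run, "conditioning", beh)


def probe_run_events(
    cfg: SimConfig, rng: np.random.Generator, subject: int,
    probe: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    beh = probe[probe["subject"] == subject]
    return _prediction_trial_rows(cfg, rng, subject, 1, "probe", beh)
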