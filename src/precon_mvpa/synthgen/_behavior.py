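"""Behavioral simulation: learning curves, RTs, recognition memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from precon_mvpa.behav_stats import BehaviorTable
from precon_mvpa.config import SimConfig


def _learning_prob(cfg: SimConfig, role: str, rep: int) -> float:
    """P(predict reward) for cue B/D at global repetition ``rep`` (1-based)."""
    asym = cfg.asymptote_hi if role == "B" else cfg.asymptote_lo
    return 0.5 + (asym - 0.5) * (1.0 - np.exp(-cfg.learning_rate * rep))


def _inference_strength(cfg: SimConfig, dprime: float) -> float:
    """Probe-phase A/C separation as a logistic function of latent d'."""
    if cfg.dprime_inference_coupling == 0:
        return 0.0
    return float(expit(cfg.dprime_inference_coupling * (dprime - 1.0)))


def simulate_behavior(cfg: SimConfig, seed: int | None = None) -> BehaviorTable:
    """Generate the cohort's behavioral data with known structure.

    Reward-prediction probabilities for cues B/D follow saturating
    learning curves; probe responding to A/C scales with each subject's
    latent recognition sensitivity; response times fall across
    preconditioning runs and are slower for preconditioned than
    conditioned cues at probe. A small configurable fraction of trials
    are non-responses.
    """
    seed = cfg.seed if seed is None else seed
    n_reps = cfg.n_cond_runs * cfg.cond_reps_per_run
    cond_rows, probe_rows, precond_rows, recog_rows = [], [], [], []

    for s in range(cfg.n_subjects):
        rng = np.random.default_rng([seed, 7001, s])
        latent_dprime = cfg.dprime_mean + cfg.dprime_sd * rng.standard_normal()

        # --- preconditioning catch-trial RTs --------------------------
        n_trials = 2 * cfg.n_cue_sets + cfg.n_control_pairs
        n_catch = int(round(cfg.precond_catch_rate * n_trials))
        if cfg.precond_catch_rate > 0:
            n_catch = max(n_catch, 2)    # keep per-run RT means defined
        for run in range(1, cfg.n_precond_runs + 1):
            catch_idx = set(rng.choice(n_trials, size=n_catch, replace=False))
            for trial in range(n_trials):
                is_catch = trial in catch_idx
                rt = np.nan
                if is_catch:
                    rt = max(0.2, cfg.rt_intercept_s
                             + cfg.rt_slope_s * (run - 1)
                             + cfg.rt_noise_sd_s * rng.standard_normal())
                precond_rows.append({
                    "subject": s, "run": run, "trial": trial,
                    "is_catch": is_catch, "response_time": rt})

        # --- conditioning ---------------------------------------------
        for role in ("B", "D"):
            for cue_set in range(1, cfg.n_cue_sets + 1):
                for rep in range(1, n_reps + 1):
                    run = (rep - 1) // cfg.cond_reps_per_run + 1
                    if rng.random() < cfg.nonresponse_rate:
                        resp, rt = "none", np.nan
                    else:
                        p = _learning_prob(cfg, role, rep)
                        resp = "plus" if rng.random() < p else "minus"
                        speedup = 0.02 * rep if role == "B" else 0.005 * rep
                        rt = float(np.clip(
                            cfg.rt_intercept_s - speedup
                            + (0.05 if role == "D" else 0.0)
                            + cfg.rt_noise_sd_s * rng.standard_normal(),
                            0.2, 1.4))
                    cond_rows.append({
                        "subject": s, "run": run, "repetition": rep,
                        "cue_role": role, "cue_set": cue_set,
                        "response": resp, "response_time": rt})

        # --- probe -----------------------------------------------------
        strength = _inference_strength(cfg, latent_dprime)
        p_plus = {
            "B": _learning_prob(cfg, "B", n_reps),
            "D": _learning_prob(cfg, "D", n_reps),
            "A": 0.5 + 0.45 * strength,
            "C": 0.5 - 0.45 * strength,
        }
        for role in ("A", "B", "C", "D"):
            for cue_set in range(1, cfg.n_cue_sets + 1):
                for rep in range(1, cfg.probe_reps + 1):
                    if rng.random() < cfg.nonresponse_rate:
                        resp, rt = "none", np.nan
                    else:
                        resp = "plus" if rng.random() < p_plus[role] else "minus"
                        rt = float(np.clip(
                            cfg.rt_intercept_s
                            + (0.15 if role in ("A", "C") else 0.0)
                            + cfg.rt_noise_sd_s * rng.standard_normal(),
                            0.2, 1.4))
                    probe_rows.append({
                        "subject": s, "run": 1, "repetition": rep,
                        "cue_role": role, "cue_set": cue_set,
                        "response": resp, "response_time": rt})

        # --- recognition test ------------------------------------------
        p_hit = float(norm.cdf(latent_dprime / 2.0))
        p_fa = float(norm.cdf(-latent_dprime / 2.0))
        hits = int(rng.binomial(cfg.n_recognition_old, p_hit))
        fas = int(rng.binomial(cfg.n_recognition_recombined, p_fa))
        recog_rows.append({
            "subject": s,
            "hits": hits,
            "misses": cfg.n_recognition_old - hits,
            "false_alarms": fas,
            "correct_rejections": cfg.n_recognition_recombined - fas,
            "latent_dprime": latent_dprime,
        })

    precond_trials = pd.DataFrame(precond_rows)
    responded = precond_trials[precond_trials["response_time"].notna()]
    precond_rt = (responded.groupby(["subject", "run"])["response_time"]
                  .agg(["mean", "size"]).reset_index()
                  .rename(columns={"mean": "mean_rt", "size": "n_responses"}))

    return BehaviorTable(
        conditioning=pd.DataFrame(cond_rows),
        probe=pd.DataFrame(probe_rows),
        precond_rt=precond_rt,
        recognition=pd.DataFrame(recog_rows),
        precond_trials=precond_trials,
    )
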