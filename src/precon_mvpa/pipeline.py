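"""End-to-end orchestration of the analysis stages over a dataset.

Each stage consumes a :class:`~precon_mvpa.synthgen.SyntheticDataset`
(or an equivalently structured dataset loaded from disk) and emits tidy
result tables. The command-line interface wraps these functions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from precon_mvpa import behav_stats, conn, decode, rsa
from precon_mvpa.behav_stats import StatResult
from precon_mvpa.config import RunConfig
from precon_mvpa.glm import PatternEstimates, build_design, fit_glm
from precon_mvpa.synthgen import SubjectData, SyntheticDataset

__all__ = [
    "SubjectEstimates",
    "similarity_stage",
    "reactivation_stage",
    "decoding_stage",
    "connectivity_stage",
    "behavior_stage",
    "run_all",
]

_CONDITION_RE = re.compile(r"^([ABCDE])(\d*)$")

#: conditioning runs used for decoder training (behavior stabilizes
#: after the first two runs; the last three are used)
N_TRAIN_RUNS = 3


def _condition_labels(names: list[str], phase: str, run: int) -> pd.DataFrame:
    rows = []
    for name in names:
        m = _CONDITION_RE.match(name)
        if m:
            role, cue_set = m.group(1), m.group(2)
            rows.append({"condition": name, "phase": phase, "run": run,
                         "cue_role": role,
                         "cue_set": int(cue_set) if cue_set else np.nan})
        else:
            rows.append({"condition": name, "phase": phase, "run": run,
                         "cue_role": np.nan, "cue_set": np.nan})
    return pd.DataFrame(rows)


class SubjectEstimates:
    """Lazily fitted, cached first-level estimates for one subject."""

    def __init__(self, sub: SubjectData, tr_s: float):
        self.sub = sub
        self.tr_s = tr_s
        self._cache: dict = {}

    def fit(self, phase: str, run: int, roi: str,
            scheme: str = "by_role") -> PatternEstimates:
        key = (phase, run, roi, scheme)
        if key not in self._cache:
            events = self.sub.events[(phase, run)]
            design = build_design(
                events,
                n_volumes=self.sub.n_volumes[(phase, run)],
                tr_s=self.tr_s,
                nuisance=self.sub.nuisance[(phase, run)],
                scheme=scheme,
            )
            est = fit_glm(self.sub.bold[(phase, run, roi)], design,
                          labels=_condition_labels(design.condition_names,
                                                   phase, run),
                          roi=roi)
            self._cache[key] = est
        return self._cache[key]

    def concat(self, keys: list[tuple[str, int, str, str]]) -> PatternEstimates:
        """Stack estimates from several runs into one collection."""
        ests = [self.fit(*k) for k in keys]
        return PatternEstimates(
            betas=np.vstack([e.betas for e in ests]),
            tvals=np.vstack([e.tvals for e in ests]),
            df_resid=min(e.df_resid for e in ests),
            labels=pd.concat([e.labels for e in ests], ignore_index=True),
            roi=ests[0].roi,
        )

    def train_runs(self) -> list[int]:
        runs = self.sub.runs("conditioning")
        return runs[-N_TRAIN_RUNS:]


# ---------------------------------------------------------------------------
# similarity / reactivation
# ---------------------------------------------------------------------------

def similarity_stage(
    ds: SyntheticDataset, run_cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-minus-unpaired similarity trajectories plus group trend tests."""
    traj_rows = []
    for sub in ds.subjects:
        se = SubjectEstimates(sub, ds.cfg.tr_s)
        for roi in run_cfg.rois:
            runs = sub.runs("preconditioning")
            ests = [se.fit("preconditioning", r, roi) for r in runs]
            traj = rsa.paired_contrast_trajectory(ests,
                                                  use_tmaps=run_cfg.use_tmaps)
            traj.insert(0, "subject", sub.subject)
            traj_rows.append(traj)
    table = pd.concat(traj_rows, ignore_index=True)

    trend_rows = []
    for roi in run_cfg.rois:
        sub_table = table[table["roi"] == roi][["subject", "run", "delta"]]
        slopes, result = rsa.linear_trend_test(sub_table, tail=run_cfg.tail)
        trend_rows.append({"roi": roi, **result.to_dict(),
                           "mean_slope": float(np.mean(slopes))})
    return table, pd.DataFrame(trend_rows)


def reactivation_stage(
    ds: SyntheticDataset, run_cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reactivation contrasts: conditioning-BD, probe-AC, day-corrected."""
    rows = []
    for sub in ds.subjects:
        se = SubjectEstimates(sub, ds.cfg.tr_s)
        pre_runs = sub.runs("preconditioning")
        first_run, last_run = pre_runs[0], pre_runs[-1]
        for roi in run_cfg.rois:
            first = se.fit("preconditioning", first_run, roi)
            last = se.fit("preconditioning", last_run, roi)
            cond_template = se.concat(
                [("conditioning", r, roi, "by_role")
                 for r in sub.runs("conditioning")])
            probe_template = se.fit("probe", 1, roi, scheme="by_cue")

            val_bd = rsa.reactivation_contrast(
                cond_template, first, last, roles=("B", "D"),
                use_tmaps=run_cfg.use_tmaps)
            val_ac = rsa.reactivation_contrast(
                probe_template, first, last, roles=("A", "C"),
                use_tmaps=run_cfg.use_tmaps)
            control = rsa.scanday_control_contrast(
                probe_template, first, last, roles=("A", "C"),
                control_map={"A": "C", "C": "A"},
                use_tmaps=run_cfg.use_tmaps)
            rows += [
                {"subject": sub.subject, "roi": roi,
                 "variant": "conditioning-BD", "value": val_bd},
                {"subject": sub.subject, "roi": roi,
                 "variant": "probe-AC", "value": val_ac},
                {"subject": sub.subject, "roi": roi,
                 "variant": "probe-AC-daycorrected",
                 "value": float(rsa.scanday_corrected_contrast(
                     np.array([val_ac]), np.array([control]))[0])},
            ]
    table = pd.DataFrame(rows)
    group_rows = []
    for (roi, variant), grp in table.groupby(["roi", "variant"]):
        result = behav_stats.group_t(grp["value"], 0.0, tail=run_cfg.tail,
                                     name=f"reactivation[{variant}]")
        group_rows.append({"roi": roi, "variant": variant, **result.to_dict()})
    return table, pd.DataFrame(group_rows)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _label_value(role: str) -> int:
    return decode.REWARD_LABEL if role in ("B", "A") else decode.NONREWARD_LABEL


def build_subject_patterns(
    se: SubjectEstimates, roi: str, test_roles: tuple[str, str],
    use_tmaps: bool = True,
) -> decode.SubjectPatterns:
    """Training (conditioning, pooled roles) and test (probe, per-cue) data."""
    train = se.concat([("conditioning", r, roi, "by_role")
                       for r in se.train_runs()]).select(cue_role=["B", "D"])
    test = se.fit("probe", 1, roi, scheme="by_cue").select(
        cue_role=list(test_roles))
    return decode.SubjectPatterns(
        train_X=train.patterns(use_tmaps),
        train_y=np.array([_label_value(r) for r in train.labels["cue_role"]]),
        test_X=test.patterns(use_tmaps),
        test_y=np.array([_label_value(r) for r in test.labels["cue_role"]]),
    )


def _cross_set_tables(
    se: SubjectEstimates, roi: str, test_roles: tuple[str, str],
    n_sets: int, use_tmaps: bool = True,
):
    train_all = se.concat([("conditioning", r, roi, "by_cue")
                           for r in se.train_runs()])
    test_all = se.fit("probe", 1, roi, scheme="by_cue")
    train_by_set, test_by_set = {}, {}
    for cue_set in range(1, n_sets + 1):
        tr = train_all.select(cue_role=["B", "D"], cue_set=cue_set)
        te = test_all.select(cue_role=list(test_roles), cue_set=cue_set)
        train_by_set[cue_set] = (
            tr.patterns(use_tmaps),
            np.array([_label_value(r) for r in tr.labels["cue_role"]]))
        test_by_set[cue_set] = (
            te.patterns(use_tmaps),
            np.array([_label_value(r) for r in te.labels["cue_role"]]))
    return train_by_set, test_by_set


def decoding_stage(
    ds: SyntheticDataset, run_cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-set (B-vs-D, A-vs-C) and cross-set decoding per ROI."""
    per_subject, group_rows = [], []
    estimates = {sub.subject: SubjectEstimates(sub, ds.cfg.tr_s)
                 for sub in ds.subjects}
    for roi in run_cfg.rois:
        step = run_cfg.feature_steps.get(roi, 40)
        spec = decode.DecodeSpec(
            feature_step=step, svm_cost=run_cfg.svm_cost,
            n_permutations=run_cfg.n_permutations, seed=run_cfg.seed,
            tail=run_cfg.tail)
        for scheme, roles in (("bd", ("B", "D")), ("ac", ("A", "C"))):
            data = {subj: build_subject_patterns(se, roi, roles,
                                                 run_cfg.use_tmaps)
                    for subj, se in estimates.items()}
            outcome = decode.decode_cohort(data, spec, scheme=scheme, roi=roi)
            t = outcome.table.copy()
            t.insert(1, "roi", roi)
            t.insert(2, "scheme", scheme)
            per_subject.append(t)
            group_rows.append({"roi": roi, "scheme": scheme,
                               **outcome.group.to_dict()})

        # leave-one-cue-set-out, tested on the held-out set's A/C probes
        rows = []
        for idx, (subj, se) in enumerate(estimates.items()):
            train_by_set, test_by_set = _cross_set_tables(
                se, roi, ("A", "C"), ds.cfg.n_cue_sets, run_cfg.use_tmaps)
            acc, _, pred, labels = decode.cross_set_decode(
                train_by_set, test_by_set, spec)
            chance = decode.empirical_chance(
                pred, labels, spec.n_permutations, seed=spec.seed + idx)
            rows.append({"subject": subj, "roi": roi, "scheme": "cross-set",
                         "accuracy": acc, "chance": chance,
                         "n_voxels": ds.cfg.n_voxels_per_roi[roi]})
        cs = pd.DataFrame(rows)
        per_subject.append(cs)
        result = behav_stats.group_t(cs["accuracy"] - cs["chance"], 0.0,
                                     tail=run_cfg.tail,
                                     name="accuracy_vs_chance")
        group_rows.append({"roi": roi, "scheme": "cross-set",
                           **result.to_dict()})
    return (pd.concat(per_subject, ignore_index=True),
            pd.DataFrame(group_rows))


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def connectivity_stage(
    ds: SyntheticDataset, run_cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PPI contrast per subject plus group test and RT correlation."""
    seed_roi = ds.ground_truth.coupling_seed_roi
    target_roi = ds.ground_truth.coupling_target_roi
    rows = []
    for sub in ds.subjects:
        events = sub.events[("probe", 1)]
        seed_tc = conn.seed_timecourse(sub.bold[("probe", 1, seed_roi)])
        target = sub.bold[("probe", 1, target_roi)].mean(axis=1)
        est = conn.ppi_fit(seed_tc, events, target, ds.cfg.tr_s,
                           nuisance=sub.nuisance[("probe", 1)],
                           seed_name=seed_roi, target_name=target_roi)
        rows.append({"subject": sub.subject,
                     "beta_precond": est.beta_precond,
                     "beta_cond": est.beta_cond,
                     "contrast": est.contrast})
    table = pd.DataFrame(rows)
    group = behav_stats.group_t(table["contrast"], 0.0, tail=run_cfg.tail,
                                name="ppi_contrast")

    probe = ds.behavior.probe
    rt = (probe[probe["cue_role"].isin(["A", "C"])]
          .groupby("subject")["response_time"].mean())
    merged = table.set_index("subject").join(rt.rename("rt"))
    corr = conn.connectivity_behavior_correlation(
        merged["contrast"], merged["rt"], tail="less")
    stats_table = pd.DataFrame([
        {"test": "ppi_contrast", **group.to_dict()},
        {"test": "contrast_vs_rt", **corr.to_dict()},
    ])
    return table, stats_table


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def behavior_stage(ds: SyntheticDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Learning curves and the full set of behavioral group statistics."""
    beh = ds.behavior
    curves = behav_stats.prediction_curves(beh.conditioning)
    stats_rows: list[dict] = []

    def add(result: StatResult, test: str) -> None:
        stats_rows.append({"test": test, **result.to_dict()})

    # preconditioning RT: per-subject linear trend across runs
    rt_wide = beh.precond_rt.pivot(index="subject", columns="run",
                                   values="mean_rt")
    _, rt_trend = rsa.linear_trend_test(rt_wide.to_numpy(), tail="less")
    add(rt_trend, "precond_rt_trend")

    # conditioning: cue x repetition RM-ANOVA on % reward predicted and RT
    for dv, label in (("pct_reward_predicted", "prediction"),
                      ("mean_rt", "rt")):
        for res in behav_stats.rm_anova(curves, dv,
                                        within=["cue_role", "repetition"]):
            add(res, f"conditioning_{label}_anova[{res.name}]")

    # probe: % reward predicted per role; paired tests and ANOVA
    probe_curves = behav_stats.prediction_curves(beh.probe)
    probe_pct = probe_curves.groupby(["subject", "cue_role"])[
        "pct_reward_predicted"].mean().unstack()
    add(behav_stats.group_t(probe_pct["B"], tail="greater",
                            paired_with=probe_pct["D"]), "probe_B_vs_D")
    add(behav_stats.group_t(probe_pct["A"], tail="greater",
                            paired_with=probe_pct["C"]), "probe_A_vs_C")

    # recognition d' and its correlation with inference success
    recog = beh.recognition.copy()
    recog["dprime"] = [
        behav_stats.dprime(r.hits, r.misses, r.false_alarms,
                           r.correct_rejections)
        for r in recog.itertuples()]
    inference = (probe_pct["A"] - probe_pct["C"]).rename("a_minus_c")
    joined = recog.set_index("subject").join(inference)
    add(behav_stats.pearson_correlation(joined["dprime"],
                                        joined["a_minus_c"],
                                        tail="greater"),
        "dprime_vs_inference")

    # exclusion rule
    retained, exclusion = behav_stats.exclusion_filter(beh)
    stats_rows.append({"test": "exclusion", "name": "retained_subjects",
                       "statistic": float(len(retained)), "df1": np.nan,
                       "df2": np.nan, "epsilon": np.nan, "p": np.nan,
                       "tail": ""})
    stats = pd.DataFrame(stats_rows)
    curves = curves.assign(phase="conditioning")
    curves = pd.concat([curves, probe_curves.assign(phase="probe")],
                       ignore_index=True)
    return curves, stats


# ---------------------------------------------------------------------------
# everything
# ---------------------------------------------------------------------------

def run_all(ds: SyntheticDataset, run_cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage; returns a name -> table mapping."""
    similarity, similarity_trend = similarity_stage(ds, run_cfg)
    reactivation, reactivation_group = reactivation_stage(ds, run_cfg)
    decoding, decoding_group = decoding_stage(ds, run_cfg)
    connectivity, connectivity_stats = connectivity_stage(ds, run_cfg)
    curves, behavior_statistics = behavior_stage(ds)
    return {
        "similarity": similarity,
        "similarity_trend": similarity_trend,
        "reactivation": reactivation,
        "reactivation_group": reactivation_group,
        "decoding": decoding,
        "decoding_group": decoding_group,
        "connectivity": connectivity,
        "connectivity_stats": connectivity_stats,
        "behavior_curves": curves,
        "behavior_stats": behavior_statistics,
    }
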