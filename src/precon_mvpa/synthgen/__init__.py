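"""Synthetic sensory-preconditioning experiments with known ground truth.

:func:`simulate_dataset` produces, for every subject, event tables,
ROI-wise BOLD series, nuisance series and behavioral tables, with the
statistical structure each downstream analysis stage assumes planted at
configurable amplitudes: cue-cue pattern convergence across
preconditioning, an outcome-value axis in the designated "OFC-like"
ROI, probe-phase reactivation of paired-cue patterns, and context-
dependent seed-target coupling for the connectivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from precon_mvpa.behav_stats import BehaviorTable
from precon_mvpa.config import SimConfig, save_sim_config, load_sim_config
from precon_mvpa.ioconfig.events import validate_events, write_events, read_events
from precon_mvpa.ioconfig.volumes import RoiMask, save_volume, read_volume, mask_to_array
from precon_mvpa.synthgen._behavior import simulate_behavior
from precon_mvpa.synthgen._bold import (
    convolved_cue_regressors, respiration_like_nuisance, synthesize_run_bold,
)
from precon_mvpa.synthgen._patterns import LatentPatterns, SubjectEffects
from precon_mvpa.synthgen._schedule import (
    cond_run_events, precond_run_events, probe_run_events,
)

__all__ = [
    "simulate_dataset", "simulate_behavior", "build_masks",
    "SyntheticDataset", "SubjectData", "SyntheticGroundTruth",
    "save_dataset", "load_dataset", "LatentPatterns", "SubjectEffects",
]

#: baseline seed-target coupling present in both contexts
_BASE_COUPLING = 0.2


@dataclass
class SubjectData:
    """All simulated data for one subject."""

    subject: int
    events: dict          # (phase, run) -> DataFrame
    bold: dict            # (phase, run, roi) -> (volumes x voxels)
    nuisance: dict        # (phase, run) -> (volumes,) array
    n_volumes: dict       # (phase, run) -> int
    latents: dict | None = None    # roi -> LatentPatterns (in-memory only)

    def runs(self, phase: str) -> list[int]:
        return sorted(r for (ph, r) in self.events if ph == phase)


@dataclass
class SyntheticGroundTruth:
    """Planted effect sizes and generation parameters."""

    effects: pd.DataFrame       # one row per subject
    value_roi: str
    coupling_seed_roi: str
    coupling_target_roi: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.to_dict(orient="list"),
            "value_roi": self.value_roi,
            "coupling_seed_roi": self.coupling_seed_roi,
            "coupling_target_roi": self.coupling_target_roi,
            "config": self.config,
        }


@dataclass
class SyntheticDataset:
    cfg: SimConfig
    masks: dict                     # roi -> RoiMask
    subjects: list                  # list[SubjectData]
    behavior: BehaviorTable
    ground_truth: SyntheticGroundTruth


def build_masks(cfg: SimConfig) -> dict[str, RoiMask]:
    """Disjoint cuboid ROI masks on a shared lattice."""
    rois = list(cfg.n_voxels_per_roi)
    ny, nz = 5, 4
    offset = 0
    blocks = {}
    for roi in rois:
        n = cfg.n_voxels_per_roi[roi]
        nx = int(np.ceil(n / (ny * nz)))
        coords = [(offset + x, y, z)
                  for x in range(nx) for y in range(ny) for z in range(nz)]
        blocks[roi] = np.asarray(coords[:n], dtype=int)
        offset += nx + 2            # gap between ROIs
    shape = (offset, ny, nz)
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    return {roi: RoiMask(name=roi, shape=shape, affine=affine, indices=idx)
            for roi, idx in blocks.items()}


def _subject_effects(cfg: SimConfig, rng: np.random.Generator,
                     latent_dprime: float) -> SubjectEffects:
    vals = {
        "similarity_slope": cfg.similarity_slope,
        "value_amplitude": cfg.value_amplitude,
        "reactivation_gain": cfg.reactivation_gain,
        "coupling_modulation": cfg.coupling_modulation,
    }
    if cfg.random_effects:
        for key in vals:
            vals[key] *= max(0.0, 1.0 + cfg.random_effects_cv
                             * rng.standard_normal())
    vals["reactivation_gain"] = min(vals["reactivation_gain"], 1.0)
    return SubjectEffects(dprime=latent_dprime, **vals)


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort. Deterministic in ``cfg.seed``."""
    masks = build_masks(cfg)
    behavior = simulate_behavior(cfg)
    rois = list(cfg.n_voxels_per_roi)
    # seed ROI first so the coupling term can reference its timecourse
    ordered_rois = ([cfg.coupling_seed_roi]
                    + [r for r in rois if r != cfg.coupling_seed_roi])

    subjects = []
    effect_rows = []
    for s in range(cfg.n_subjects):
        latent_dprime = float(
            behavior.recognition.loc[behavior.recognition["subject"] == s,
                                     "latent_dprime"].iloc[0])
        eff = _subject_effects(
            cfg, np.random.default_rng([cfg.seed, 300, s]), latent_dprime)
        effect_rows.append({"subject": s, **eff.__dict__})

        latents = {
            roi: LatentPatterns(cfg, roi,
                                np.random.default_rng([cfg.seed, 400, s, i]),
                                eff)
            for i, roi in enumerate(rois)
        }

        events, bold, nuisance, n_volumes = {}, {}, {}, {}
        run_list = (
            [("preconditioning", r) for r in range(1, cfg.n_precond_runs + 1)]
            + [("conditioning", r) for r in range(1, cfg.n_cond_runs + 1)]
            + [("probe", 1)]
        )
        for phase_idx, (phase, run) in enumerate(run_list):
            sched_rng = np.random.default_rng([cfg.seed, 500, s, phase_idx])
            if phase == "preconditioning":
                ev, nvol = precond_run_events(
                    cfg, sched_rng, s, run, behavior.precond_trials)
            elif phase == "conditioning":
                ev, nvol = cond_run_events(
                    cfg, sched_rng, s, run, behavior.conditioning)
            else:
                ev, nvol = probe_run_events(cfg, sched_rng, s, behavior.probe)
            validate_events(ev)
            events[(phase, run)] = ev
            n_volumes[(phase, run)] = nvol
            nuisance[(phase, run)] = respiration_like_nuisance(
                np.random.default_rng([cfg.seed, 600, s, phase_idx]),
                nvol, cfg.tr_s)

            for roi_idx, roi in enumerate(ordered_rois):
                noise_rng = np.random.default_rng(
                    [cfg.seed, 700, s, phase_idx, roi_idx])
                series = synthesize_run_bold(
                    cfg, ev, nvol, latents[roi], noise_rng,
                    nuisance[(phase, run)])
                if phase == "probe" and roi == cfg.coupling_target_roi:
                    seed_series = (series
                                   if roi == cfg.coupling_seed_roi
                                   else bold[(phase, run,
                                              cfg.coupling_seed_roi)])
                    series = series + _coupling_term(
                        cfg, ev, nvol, seed_series,
                        eff.coupling_modulation)[:, None]
                bold[(phase, run, roi)] = series

        subjects.append(SubjectData(subject=s, events=events, bold=bold,
                                    nuisance=nuisance, n_volumes=n_volumes,
                                    latents=latents))

    truth = SyntheticGroundTruth(
        effects=pd.DataFrame(effect_rows),
        value_roi=cfg.value_roi,
        coupling_seed_roi=cfg.coupling_seed_roi,
        coupling_target_roi=cfg.coupling_target_roi,
        config=cfg.to_dict(),
    )
    return SyntheticDataset(cfg=cfg, masks=masks, subjects=subjects,
                            behavior=behavior, ground_truth=truth)


def _coupling_term(cfg: SimConfig, events: pd.DataFrame, n_volumes: int,
                   seed_bold: np.ndarray, coupling_modulation: float,
                   ) -> np.ndarray:
    """Context-dependent seed-coupled signal added to every target voxel."""
    seed_tc = seed_bold.mean(axis=1)
    seed_tc = seed_tc - seed_tc.mean()
    regs, identity = convolved_cue_regressors(events, n_volumes, cfg.tr_s)
    x_pre = np.zeros(n_volumes)
    x_cond = np.zeros(n_volumes)
    for name, reg in regs.items():
        role = identity[name][1]
        if role in ("A", "C"):
            x_pre += reg
        elif role in ("B", "D"):
            x_cond += reg
    gamma_pre = _BASE_COUPLING + coupling_modulation
    gamma_cond = _BASE_COUPLING
    return seed_tc * (gamma_pre * x_pre + gamma_cond * x_cond)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a dataset as events TSV + NIfTI volumes + JSON ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_sim_config(ds.cfg, out / "config.yaml")
    for roi, mask in ds.masks.items():
        save_volume(mask_to_array(mask), mask.affine,
                    out / "masks" / f"{roi}.nii.gz")
    for sub in ds.subjects:
        sdir = out / f"sub-{sub.subject:02d}"
        for (phase, run), ev in sub.events.items():
            stem = f"phase-{phase}_run-{run}"
            write_events(ev, sdir / f"{stem}_events.tsv")
            pd.DataFrame({"nuisance_0": sub.nuisance[(phase, run)]}).to_csv(
                sdir / f"{stem}_nuisance.tsv", sep="\t", index=False)
            for roi in ds.masks:
                mask = ds.masks[roi]
                vol = np.zeros(mask.shape + (sub.n_volumes[(phase, run)],),
                               dtype=np.float32)
                i, j, k = mask.indices.T
                vol[i, j, k, :] = sub.bold[(phase, run, roi)].T
                save_volume(vol, mask.affine,
                            sdir / f"{stem}_bold_{roi}.nii.gz")
    bdir = out / "behavior"
    bdir.mkdir(exist_ok=True)
    for name in ("conditioning", "probe", "precond_rt", "recognition",
                 "precond_trials"):
        table = getattr(ds.behavior, name)
        if table is not None:
            table.to_csv(bdir / f"{name}.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ds.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Reload a saved dataset (latent patterns are not persisted)."""
    root = Path(in_dir)
    cfg = load_sim_config(root / "config.yaml")
    masks = {roi: read_volume(root / "masks" / f"{roi}.nii.gz")
             for roi in cfg.n_voxels_per_roi}
    subjects = []
    for s in range(cfg.n_subjects):
        sdir = root / f"sub-{s:02d}"
        events, bold, nuisance, n_volumes = {}, {}, {}, {}
        for ev_path in sorted(sdir.glob("phase-*_events.tsv")):
            stem = ev_path.name.replace("_events.tsv", "")
            phase = stem.split("_")[0].split("-", 1)[1]
            run = int(stem.split("_")[1].split("-", 1)[1])
            ev = read_events(ev_path)
            events[(phase, run)] = ev
            nuisance[(phase, run)] = pd.read_csv(
                sdir / f"{stem}_nuisance.tsv", sep="\t")["nuisance_0"].to_numpy()
            for roi, mask in masks.items():
                data, _ = read_volume(sdir / f"{stem}_bold_{roi}.nii.gz",
                                      expect_4d=True)
                bold[(phase, run, roi)] = mask.extract(data)
                n_volumes[(phase, run)] = data.shape[3]
        subjects.append(SubjectData(subject=s, events=events, bold=bold,
                                    nuisance=nuisance, n_volumes=n_volumes))
    behavior = BehaviorTable(
        conditioning=pd.read_csv(root / "behavior/conditioning.tsv", sep="\t"),
        probe=pd.read_csv(root / "behavior/probe.tsv", sep="\t"),
        precond_rt=pd.read_csv(root / "behavior/precond_rt.tsv", sep="\t"),
        recognition=pd.read_csv(root / "behavior/recognition.tsv", sep="\t"),
        precond_trials=pd.read_csv(root / "behavior/precond_trials.tsv",
                                   sep="\t"),
    )
    with open(root / "ground_truth.json") as fh:
        gt = json.load(fh)
    truth = SyntheticGroundTruth(
        effects=pd.DataFrame(gt["effects"]),
        value_roi=gt["value_roi"],
        coupling_seed_roi=gt["coupling_seed_roi"],
        coupling_target_roi=gt["coupling_target_roi"],
        config=gt["config"],
    )
    return SyntheticDataset(cfg=cfg, masks=masks, subjects=subjects,
                            behavior=behavior, ground_truth=truth)
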