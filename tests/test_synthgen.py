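"""Synthetic-data generator tests: determinism, design counts, planted
structure, behavioral model, and the on-disk round trip."""

import numpy as np
import pandas as pd
import pytest

from precon_mvpa import behav_stats
from precon_mvpa.config import ConfigError, RunConfig, SimConfig
from precon_mvpa.synthgen import (
    build_masks, load_dataset, save_dataset, simulate_behavior,
    simulate_dataset,
)
from precon_mvpa.synthgen._behavior import _learning_prob
from tests.conftest import small_sim_config


class TestConfigValidation:
    def test_defaults_match_study_design(self):
        cfg = SimConfig()
        assert cfg.n_subjects == 24
        assert cfg.n_cue_sets == 8
        assert (cfg.n_precond_runs, cfg.n_cond_runs, cfg.n_probe_runs) == (4, 5, 1)
        assert cfg.n_cond_runs * cfg.cond_reps_per_run == 10
        assert cfg.probe_reps == 4

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ConfigError, match="basis"):
            small_sim_config(n_voxels_per_roi={"ofc_medial": 10,
                                               "hpc_posterior": 48})

    @pytest.mark.parametrize("bad", [
        {"ar1": 1.0}, {"ar1": -0.1}, {"noise_sd": 0.0},
        {"n_subjects": 0}, {"reactivation_gain": 1.5},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ConfigError):
            small_sim_config(**bad)


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        cfg = small_sim_config(n_subjects=2)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        for key in a.subjects[0].bold:
            np.testing.assert_array_equal(a.subjects[0].bold[key],
                                          b.subjects[0].bold[key])
        for key in a.subjects[1].events:
            pd.testing.assert_frame_equal(a.subjects[1].events[key],
                                          b.subjects[1].events[key])
        pd.testing.assert_frame_equal(a.behavior.probe, b.behavior.probe)

    def test_different_seed_different_noise(self):
        a = simulate_dataset(small_sim_config(n_subjects=1, seed=1))
        b = simulate_dataset(small_sim_config(n_subjects=1, seed=2))
        key = ("probe", 1, "ofc_medial")
        assert not np.array_equal(a.subjects[0].bold[key],
                                  b.subjects[0].bold[key])


class TestDesignStructure:
    def test_run_inventory(self, tiny_dataset, tiny_cfg):
        sub = tiny_dataset.subjects[0]
        assert sub.runs("preconditioning") == list(
            range(1, tiny_cfg.n_precond_runs + 1))
        assert sub.runs("conditioning") == list(
            range(1, tiny_cfg.n_cond_runs + 1))
        assert sub.runs("probe") == [1]

    def test_cue_counts_per_run(self, tiny_dataset, tiny_cfg):
        sub = tiny_dataset.subjects[0]
        pre = sub.events[("preconditioning", 1)]
        cues = pre[pre["trial_type"] == "cue"]
        counts = cues["cue_role"].value_counts()
        for role in "ABCD":
            assert counts[role] == tiny_cfg.n_cue_sets
        assert counts["E"] == 2 * tiny_cfg.n_control_pairs

        cond = sub.events[("conditioning", 1)]
        ccues = cond[cond["trial_type"] == "cue"]
        assert (ccues.groupby(["cue_role", "cue_set"]).size()
                == tiny_cfg.cond_reps_per_run).all()
        assert set(ccues["cue_role"]) == {"B", "D"}

        probe = sub.events[("probe", 1)]
        pcues = probe[probe["trial_type"] == "cue"]
        assert (pcues.groupby(["cue_role", "cue_set"]).size()
                == tiny_cfg.probe_reps).all()

    def test_events_inside_scan_window(self, tiny_dataset, tiny_cfg):
        for sub in tiny_dataset.subjects:
            for (phase, run), ev in sub.events.items():
                run_len = sub.n_volumes[(phase, run)] * tiny_cfg.tr_s
                assert ((ev["onset"] + ev["duration"]) <= run_len).all()

    def test_bold_is_finite(self, tiny_dataset):
        for key, series in tiny_dataset.subjects[0].bold.items():
            assert np.isfinite(series).all()

    def test_masks_are_disjoint_on_shared_lattice(self, tiny_cfg):
        masks = build_masks(tiny_cfg)
        seen = set()
        for roi, mask in masks.items():
            assert mask.n_voxels == tiny_cfg.n_voxels_per_roi[roi]
            vox = {tuple(v) for v in mask.indices}
            assert not (vox & seen)
            seen |= vox

    def test_ground_truth_echoes_config(self, tiny_dataset, tiny_cfg):
        eff = tiny_dataset.ground_truth.effects
        assert (eff["similarity_slope"] == tiny_cfg.similarity_slope).all()
        assert (eff["value_amplitude"] == tiny_cfg.value_amplitude).all()


class TestPlantedStructure:
    def test_latent_pair_correlation_follows_slope(self, tiny_dataset,
                                                   tiny_cfg):
        lat = tiny_dataset.subjects[0].latents["ofc_medial"]
        for run in range(1, tiny_cfg.n_precond_runs + 1):
            a = lat.precond("A", 0, run)
            b = lat.precond("B", 0, run)
            d = lat.precond("D", 0, run)
            z = np.arctanh(np.corrcoef(a, b)[0, 1])
            assert z == pytest.approx(
                tiny_cfg.similarity_slope * (run - 1), abs=1e-9)
            assert np.corrcoef(a, d)[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_null_config_has_static_orthogonal_latents(self):
        cfg = small_sim_config(n_subjects=1, similarity_slope=0.0,
                               value_amplitude=0.0, reactivation_gain=0.0,
                               coupling_modulation=0.0)
        ds = simulate_dataset(cfg)
        lat = ds.subjects[0].latents["ofc_medial"]
        a1 = lat.precond("A", 2, 1)
        a4 = lat.precond("A", 2, cfg.n_precond_runs)
        np.testing.assert_allclose(a1, a4)
        np.testing.assert_allclose(lat.probe("A", 2), a4, atol=1e-12)
        b = lat.conditioning("B", 2)
        np.testing.assert_allclose(b, lat.precond("B", 2, 4), atol=1e-12)

    def test_value_axis_only_in_value_roi(self, tiny_dataset, tiny_cfg):
        sub = tiny_dataset.subjects[0]
        for roi in tiny_cfg.n_voxels_per_roi:
            lat = sub.latents[roi]
            b = lat.conditioning("B", 1)
            d = lat.conditioning("D", 1)
            proj = (b - d) @ lat.value_axis
            if roi == tiny_cfg.value_roi:
                assert proj == pytest.approx(
                    2 * tiny_cfg.value_amplitude, abs=1e-9)
            else:
                assert proj == pytest.approx(0.0, abs=1e-9)

    def test_probe_blends_paired_cue_with_reactivation_gain(self, tiny_dataset,
                                                            tiny_cfg):
        lat = tiny_dataset.subjects[0].latents["hpc_posterior"]
        g = tiny_cfg.reactivation_gain
        last = tiny_cfg.n_precond_runs
        expected = ((1 - g) * lat.precond("A", 1, last)
                    + g * lat.precond("B", 1, last))
        np.testing.assert_allclose(lat.probe("A", 1), expected, atol=1e-12)

    def test_monotone_slope_recovery_on_grid(self):
        """Estimated similarity slope is nondecreasing in the planted one."""
        from precon_mvpa import pipeline
        recovered = []
        for slope in (0.0, 0.2, 0.5):
            cfg = small_sim_config(n_subjects=4, similarity_slope=slope,
                                   n_voxels_per_roi={"ofc_medial": 64},
                                   coupling_target_roi="ofc_medial",
                                   value_roi="ofc_medial", seed=21)
            ds = simulate_dataset(cfg)
            run_cfg = RunConfig(rois=["ofc_medial"], n_permutations=10)
            _, trend = pipeline.similarity_stage(ds, run_cfg)
            recovered.append(trend["mean_slope"].iloc[0])
        # measurement noise attenuates the absolute scale (correlations of
        # noisy t-maps shrink toward 0), but the ordering must survive
        assert recovered[0] < recovered[1] < recovered[2]


class TestBehavior:
    def test_learning_rate_zero_keeps_curves_at_chance(self):
        cfg = small_sim_config(learning_rate=0.0)
        assert _learning_prob(cfg, "B", 5) == 0.5
        assert _learning_prob(cfg, "D", 5) == 0.5
        beh = simulate_behavior(cfg, seed=2)
        curves = behav_stats.prediction_curves(beh.conditioning)
        pooled = curves.groupby("cue_role")["pct_reward_predicted"].mean()
        assert pooled["B"] == pytest.approx(50.0, abs=8.0)
        assert pooled["D"] == pytest.approx(50.0, abs=8.0)

    def test_saturating_asymptotes_reach_extremes(self):
        cfg = small_sim_config(n_subjects=8, asymptote_hi=1.0,
                               asymptote_lo=0.0, learning_rate=3.0,
                               nonresponse_rate=0.0)
        beh = simulate_behavior(cfg, seed=0)
        n_reps = cfg.n_cond_runs * cfg.cond_reps_per_run
        final = beh.conditioning[beh.conditioning["repetition"] == n_reps]
        pct = final.groupby("cue_role")["response"].apply(
            lambda s: 100 * np.mean(s == "plus"))
        assert pct["B"] > 95.0
        assert pct["D"] < 5.0

    def test_dprime_inference_coupling_sign(self):
        """Monte-Carlo over seeds: positive coupling yields a positive
        observed d'-vs-inference correlation in most cohorts."""
        positives = 0
        n_cohorts = 8
        for seed in range(n_cohorts):
            cfg = small_sim_config(n_subjects=24,
                                   dprime_inference_coupling=2.0)
            beh = simulate_behavior(cfg, seed=seed)
            probe = behav_stats.prediction_curves(beh.probe)
            pct = probe.groupby(["subject", "cue_role"])[
                "pct_reward_predicted"].mean().unstack()
            d = [behav_stats.dprime(r.hits, r.misses, r.false_alarms,
                                    r.correct_rejections)
                 for r in beh.recognition.itertuples()]
            r = behav_stats.pearson_correlation(
                d, pct["A"] - pct["C"]).statistic
            positives += r > 0
        assert positives >= n_cohorts - 1

    def test_rt_declines_across_preconditioning(self):
        cfg = small_sim_config(n_subjects=12)
        beh = simulate_behavior(cfg, seed=4)
        mean_by_run = beh.precond_rt.groupby("run")["mean_rt"].mean()
        assert mean_by_run.iloc[-1] < mean_by_run.iloc[0]

    def test_probe_rt_slower_for_preconditioned_cues(self):
        cfg = small_sim_config(n_subjects=12)
        beh = simulate_behavior(cfg, seed=4)
        rt = beh.probe.groupby("cue_role")["response_time"].mean()
        assert (rt["A"] + rt["C"]) / 2 > (rt["B"] + rt["D"]) / 2

    def test_nonresponses_present_at_configured_rate(self):
        cfg = small_sim_config(n_subjects=10, nonresponse_rate=0.1)
        beh = simulate_behavior(cfg, seed=1)
        rate = np.mean(beh.conditioning["response"] == "none")
        assert rate == pytest.approx(0.1, abs=0.03)


class TestDiskRoundTrip:
    def test_save_load_round_trip(self, tmp_path):
        cfg = small_sim_config(n_subjects=1)
        ds = simulate_dataset(cfg)
        save_dataset(ds, tmp_path / "ds")
        loaded = load_dataset(tmp_path / "ds")
        key = ("conditioning", 2, "ofc_medial")
        np.testing.assert_allclose(loaded.subjects[0].bold[key],
                                   ds.subjects[0].bold[key], rtol=1e-6)
        assert loaded.cfg.seed == cfg.seed
        ev0 = ds.subjects[0].events[("probe", 1)]
        ev1 = loaded.subjects[0].events[("probe", 1)]
        np.testing.assert_allclose(ev1["onset"], ev0["onset"])
        assert list(ev1["cue_role"].fillna("")) == list(
            ev0["cue_role"].fillna(""))
        pd.testing.assert_frame_equal(
            loaded.ground_truth.effects, ds.ground_truth.effects,
            check_dtype=False, check_like=True)
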