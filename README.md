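# precon-mvpa

A tested, reusable implementation of a pattern-based fMRI analysis
pipeline for sensory-preconditioning designs, packaged together with a
synthetic-data generator that plants every statistical structure the
analysis assumes — so each stage can be validated end to end with known
ground truth.

## What it does

A sensory-preconditioning experiment has three scanned phases: cue pairs
are learned (preconditioning, A→B / C→D plus E–E controls over 8 cue
sets), the second cue of each pair is conditioned on a monetary outcome
(B→$1, D→$0), and predictions to all cues are probed under extinction.
The pipeline implements:

- **`synthgen`** — synthetic cohorts (events TSV, ROI-wise BOLD with
  AR(1) noise, behavior tables) with configurable planted effects:
  cue–cue pattern convergence across preconditioning runs (exact
  Fisher-z trajectory at the latent level), a shared outcome-value axis
  in a designated "OFC-like" ROI, probe-phase reactivation of the paired
  cue's end-of-preconditioning pattern, and context-dependent
  seed→target coupling.
- **`glm`** — first-level pattern estimation: double-gamma HRF,
  microtime convolution sampled at volume midpoints, OLS betas and
  per-condition t-maps; role-pooled or per-cue condition schemes.
- **`rsa`** — Fisher-z paired-minus-unpaired similarity trajectories,
  per-subject linear trend tests, reactivation contrasts
  (conditioning-B/D and probe-A/C variants) and the scan-day control
  subtraction.
- **`decode`** — cross-phase linear SVM decoding (train on conditioning
  B vs D, test on probe B vs D or A vs C), absolute-t voxel ranking with
  leave-one-subject-out nested feature-count selection, leave-one-cue-
  set-out decoding, permutation-based empirical chance, and searchlight
  sphere machinery (strict-inequality radius rule; 8 mm on a 2 mm
  lattice = 251 voxels).
- **`conn`** — BOLD-level PPI: seed timecourse × HRF-convolved context
  interaction columns, per-subject coupling contrasts, and the
  connectivity–behavior correlation.
- **`behav_stats`** — learning curves, repeated-measures ANOVA with
  Greenhouse–Geisser correction, one-sample/paired t-tests, Pearson
  correlations, recognition d′ (log-linear correction), and the
  final-run binomial exclusion rule.
- **`ioconfig`** — BIDS-style events TSV, NIfTI volumes/masks, YAML
  configs, TSV result tables with JSON provenance sidecars, and the CLI.

## CLI

```bash
# simulate a cohort to disk (events TSV + NIfTI BOLD/masks + JSON truth)
precon-mvpa simulate --out scratch/ds --seed 1 --subjects 6 --voxels 200

# run individual stages against a saved dataset
precon-mvpa glm          --dataset scratch/ds --out scratch/res
precon-mvpa rsa          --dataset scratch/ds --out scratch/res
precon-mvpa decode       --dataset scratch/ds --out scratch/res
precon-mvpa connectivity --dataset scratch/ds --out scratch/res
precon-mvpa behavior     --dataset scratch/ds --out scratch/res

# or simulate in memory and run everything
precon-mvpa all --out scratch/res --seed 1 --subjects 6 --voxels 200 \
    --permutations 500
```

Every result table is a TSV with a `.json` sidecar recording the stage,
seed and configuration.

## Layout

```
src/precon_mvpa/
  config.py        simulation + analysis run configuration (YAML)
  synthgen/        synthetic experiment generator (ground truth known)
  glm.py           HRF, design matrices, OLS pattern estimation
  rsa.py           pattern-similarity analyses
  decode.py        SVM decoding, nested feature selection, searchlight
  conn.py          PPI connectivity
  behav_stats.py   behavioral summaries and shared statistics
  ioconfig/        readers/writers and the command-line interface
  pipeline.py      stage orchestration
  s1data.py        recomputation of published statistics from S1 Data
scripts/acceptance.py   acceptance-target report
tests/                  unit, property, integration and acceptance tests
```
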