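# stepgaze

Analysis pipeline for walking trials in which people negotiate a small
surface height change (a 0.075 m step-up box) while interacting with a
phone (no phone / talking / reading / writing). The package covers the
complete measurement chain:

- **`stepgaze.trial_io`** — data model and canonical I/O: marker CSV
  (`time, <marker>_x, <marker>_y, <marker>_z`), gaze CSV (`time, aoi`),
  trial metadata YAML, and a minimal C3D reader for motion-capture exports.
- **`stepgaze.synthetic_data`** — seeded generator of full trials (100 Hz
  marker trajectories, 30 Hz AOI-labelled gaze streams) from per-condition
  target means/SDs, with exact per-trial ground truth for every variable.
- **`stepgaze.gaze_pipeline`** — dwell-threshold fixation detection
  (≥ 4 consecutive same-AOI samples), tracking ratio, relative fixation
  counts/time per AOI, the first-valid-trial selection rule (tracking
  ratio ≥ 90% + good calibration), and inter-rater ICC.
- **`stepgaze.gait_pipeline`** — foot-contact detection, lead/trail limb
  assignment, sub-frame edge-crossing instant, vertical toe clearance,
  horizontal crossing velocity, stride lengths, pre/post foot placement,
  head flexion at five gait events, and medial-lateral bivariate variable
  error (BVE) of the sternum marker.
- **`stepgaze.stats_report`** — one-way repeated-measures ANOVA with
  partial eta squared, Bonferroni-corrected pairwise comparisons,
  Levene/Kolmogorov-Smirnov assumption checks, percent-change reporting
  arithmetic, and condition summary tables.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the published
percent-change comparisons, the 68/84 observation bookkeeping, oracle
equivalence for the fixation detector (run-length encoding) and the
RM-ANOVA (sums-of-squares decomposition), parameter recovery on noiseless
synthetic trials, and the qualitative condition ordering
(write > read > talk > no phone) on simulated cohorts.

## CLI

```bash
# simulate a cohort into per-trial CSV + ground-truth JSON
stepgaze simulate --design design.yaml --out data/ --seed 1

# per-trial visual-search metrics (and exclusion log)
stepgaze gaze --trials data/ --out metrics.csv

# per-trial gait parameters (set --filter-cutoff 0 to disable filtering)
stepgaze gait --trials data/ --out gait.csv --filter-cutoff 6

# condition comparisons: RM-ANOVA + pairwise, summary table
stepgaze stats --gaze metrics.csv --gait gait.csv --out report/
```

`design.yaml` may set `n_participants`, `conditions`, `repetitions` and
`between_sd_fraction`; all fields default to the study layout
(21 participants × 4 conditions × 3 repetitions).

## Conventions

- Axes: `x` anterior (toward the step), `y` medial-lateral, `z` up; SI
  units internally; toe clearance reported in mm.
- Frames are 0-based; time intervals are half-open `[start, end)`.
- "Relative number of fixations" is percent of the trial's total fixation
  count (so per-condition columns sum to ~100%); a literal per-second
  variant is available via `gaze_metrics(..., counts_per_second=True)`.
- BVE defaults to the RMS reading (root mean squared deviation about the
  trial mean); `ml_bve(..., mode="as_printed")` returns the mean squared
  deviation without the root.
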