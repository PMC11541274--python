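# gazefix

Fixation detection for **head-mounted eye tracking**, with optic-flow
head-motion compensation, flow-adaptive thresholds, event-based
post-processing, event-level evaluation, coherent parameter tuning, and a
synthetic-data generator with known ground truth.

## Why

Classical threshold-based fixation detectors (I-VT thresholds gaze *speed*,
I-DT thresholds windowed gaze *dispersion*) were designed for remote
trackers and stationary heads. A head-mounted tracker reports gaze in the
pixel space of a forward-facing scene camera, and when the observer moves,
two things break:

1. **Gaze stabilization looks like motion.** During the vestibulo-ocular
   reflex (VOR) the eye counter-rotates against the head, so a functionally
   stable fixation *co-moves with the scene-camera image content* at
   hundreds of degrees per second in camera coordinates. A fixed velocity
   threshold shreds these fixations into fragments.
2. **Noise scales with head motion.** Motion blur and tracking jitter grow
   with head-motion intensity, so a threshold tuned for quiet sitting is
   too tight for walking.

`gazefix` addresses both with signals derived from **global optic flow** of
the scene camera, a proxy for head motion:

- **Compensation** — threshold the *relative* velocity
  `v_rel = v_gaze − v_content` (or the dispersion of the flow-detrended
  trajectory) instead of the raw signal. During VOR, `v_rel ≈ 0`.
- **Adaptation** — raise the threshold linearly with the windowed RMS flow
  magnitude: `T(t) = T0 + g · o_RMS(t)` (detector variants I-VAT and
  I-DAT).
- **Event post-processing** — a micro-saccade filter (remove gaps with
  amplitude < `a_thr` **or** duration < `t_thr`) and a short-fixation
  filter (drop fixations shorter than `d_min`) repair residual
  fragmentation.
- **Event-level evaluation** — predicted and ground-truth fixations are
  matched one-to-one by temporal IoU (minimum 0.7); F1 penalizes
  fragmentation and erroneous merging three-fold. Sample-level Cohen's
  kappa is also provided.
- **Coherent tuning** — detection and post-processing parameters interact
  (a lower velocity threshold fragments more, demanding a stronger
  micro-saccade filter), so all of them are tuned *jointly* by exhaustive
  grid search with stratified k-fold cross-validation over recordings.
- **Synthesis** — a generator produces 200 Hz recordings with main-sequence
  saccades, log-normal fixation durations, VOR episodes riding a known flow
  field, and exact ground-truth events, so every stage is testable without
  recorded data. It can also render textured frame sequences realizing a
  given flow, to validate the flow estimator itself.

## Worked example

```python
import gazefix as gf
from gazefix.detectors import DetectorParams
from gazefix.optimize import Dataset, GridSpec, grid_search, evaluate_params

# 1. simulate one minute of head-mounted gaze with 300 deg/s VOR episodes
cfg = gf.SynthConfig(seed=7, duration_s=60.0, vor_prob=0.25,
                     vor_peak_dps=300.0, noise_sd_px=1.5)
rec, flow, gt = gf.generate_recording(cfg)
print(f"samples: {len(rec)}, ground-truth fixations: {len(gt.fixations())}")

# 2. coherently tune detector + post-processing on a small grid
data = Dataset([(rec, flow, gt)])
grid = GridSpec(threshold=[50, 60, 70, 80], gain=[0.0], window_ms=[205],
                a_thr=[0.0, 1.0, 1.9], t_thr_ms=[0, 10, 20, 30],
                d_min_ms=[0, 20, 40])
best, table = grid_search(data, grid, "IVT",
                          DetectorParams(compensation=True))
print(f"tuned: v_thr={best.threshold:.0f} deg/s, a_thr={best.a_thr}, "
      f"t_thr={best.t_thr_ms:.0f} ms, d_min={best.d_min_ms:.0f} ms")

# 3. evaluate the tuned compensated detector at the event level
res = evaluate_params(data, best, "IVT")
print(f"compensated I-VT:   F1={res['f1']:.3f}  kappa={res['kappa']:.3f}")

# 4. same tuning budget without head-motion compensation
best_raw, _ = grid_search(data, grid, "IVT",
                          DetectorParams(compensation=False))
res_raw = evaluate_params(data, best_raw, "IVT")
print(f"uncompensated I-VT: F1={res_raw['f1']:.3f}  "
      f"kappa={res_raw['kappa']:.3f}")
```

Output:

```
samples: 12001, ground-truth fixations: 189
tuned: v_thr=80 deg/s, a_thr=0.0, t_thr=0 ms, d_min=40 ms
compensated I-VT:   F1=0.971  kappa=0.712
uncompensated I-VT: F1=0.785  kappa=0.537
```

Head-motion compensation lifts the event-level F1 from 0.785 to 0.971 on
this VOR-heavy recording — the uncompensated detector fragments the
stabilized fixations no matter how its parameters are tuned.

Note that `DetectorParams()` defaults (`T0 = 42 °/s`, `g = 0.70`,
`w = 205 ms`, `a_thr = 1.7°`, `t_thr = 42 ms`, `d_min = 54 ms`) are mean
optimal values for naturalistic 200 Hz recordings; for any specific dataset
— including the synthetic generator, whose small saccades are briefer than
`t_thr` — the parameters should be re-tuned coherently as above.

## Command line

```bash
gazefix simulate --seed 7 --duration-s 60 --out-prefix demo      # synthesize
gazefix flow frames.tiff --fps 30 --out flow.csv                 # video -> flow
gazefix detect --gaze demo_gaze.csv --flow demo_flow.csv \
        --variant IVAT --out-events pred.csv                     # detect
gazefix evaluate --pred pred.csv --gt demo_events.csv            # score
gazefix optimize --manifest manifest.csv --grid grid.yaml \
        --folds 5 --out report.json                              # tune + CV
```

Exit codes: 0 success, 1 data error, 2 usage error. A YAML file passed via
`gazefix --config conf.yaml <command>` supplies per-command defaults.

CSV schemas (UTF-8, header mandatory): gaze `timestamp_s,x_px,y_px`, flow
`timestamp_s,u_px_s,v_px_s`, labels `timestamp_s,label`, events
`recording_id,start_s,end_s,label`.

## Reproduction

The full acceptance run (synthesis → detection → tuning → evaluation plus a
flow-estimator round trip) is scripted:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Representative output at seed 1 (about half a minute on one CPU):

| quantity | value | n |
|---|---|---|
| fixation_time_fraction | 0.839 | 120001 samples |
| main_sequence_exponent | 0.592 | 1744 saccades |
| f1_compensated_best | 0.987 | 343 fixations |
| f1_uncompensated_best | 0.695 | 343 fixations |
| f1_compensated_noise_free_best | 0.990 | 343 fixations |
| recovered_velocity_threshold | 30 | 4 recordings |
| cv_f1_mean / cv_f1_sd | 1.0 / 0.0 | 2 folds |
| flow_rms_error_px_s | 0.0013 | 9 frame pairs |
| kappa_default_detector | 0.776 | 12001 samples |

All randomness flows through `--seed`; the same seed reproduces the same
numbers bit-for-bit.

The test suite (unit, property, and acceptance tests) runs with:

```bash
python -m pytest -q tests/
```

## Documentation

See [docs/methods.md](docs/methods.md) for the signal model, parameter
semantics, the synthetic generator's scope, numerical choices, and known
limitations.
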