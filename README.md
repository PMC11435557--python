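# dynamos — voluntary-movement segmentation from a single wrist-worn IMU

Clinicians assessing upper-limb function need the onset, offset and duration
of each voluntary movement a patient performs — for example the four
sub-phases of a drinking task (reach/grasp, lift/drink, place back, return
to rest). A single wrist-worn inertial measurement unit can record these
movements at home, but segmenting its angular-velocity trace with a plain
threshold is fragile: fluctuations around the threshold fragment real
movements and bridge distinct ones.

This package implements **DynAMoS** (Dynamic Adaptive Movement
Segmentation) for tri-axial gyroscope recordings (nominally 100 Hz):

1. **Adaptive thresholding.** The channels are smoothed with a 4th-order
   zero-lag Butterworth low-pass at 1.5 Hz and reduced to the angular
   velocity norm Ω. Movement is where Ω > k·Ωmax with k = 0.11, the
   average of per-trial Otsu optima (the threshold maximizing between-class
   variance of the normalized amplitude histogram).
2. **Duration merge/split post-processing.** From the detected movement
   durations T the median M is computed and a plausibility band [αM, βM]
   defined (α = 0.8, β = 1.4). A movement shorter than αM is merged with
   its temporally nearest neighbour, but only if the summed duration falls
   inside the band; a movement longer than βM is split at an interior local
   minimum of Ω, but only if both pieces fall inside the band. M, αM and βM
   are updated after every event and the loop runs until every duration
   outlier has been processed.

Also included, so the whole workflow runs end to end:

* the two literature baselines — fixed 0.1 rad/s threshold (M1) and
  0.25·Ωmax adaptive threshold (M2);
* the stereophotogrammetric gold-standard path (marker trajectories →
  6 Hz filtering → linear-velocity norm → 0.11·vmax threshold);
* evaluation: greedy overlap matching, ErrMov, onset/offset MAE, and the
  cost Fc = Extra/Total + Missing/Total + mean|Δonset| + mean|Δoffset| +
  mean|ΔT| with an α/β grid search;
* drinking-task characterization (repetition splitting, sub-phase I–IV
  labelling, per-phase duration summaries);
* a synthetic trial generator emulating the acquisition protocol (static
  lead, optional synchronization burst, 25 repetitions × 4 sub-phases with
  ~0.97 s movements, 4 s inter-repetition rests, sensor noise and drift)
  with exact ground truth, plus controlled fragmentation/bridging
  corruption injection.

## Worked example

```python
from dynamos import (TrialSpec, generate_trial, inject_corruptions,
                     preprocess_gyro, dynamos_segments,
                     segment_fraction_of_max, match_segments, err_mov,
                     timing_errors, split_repetitions, label_subphases,
                     subphase_summary)

trial = inject_corruptions(generate_trial(TrialSpec(), seed=7),
                           fragmentation_rate=0.05, bridging_rate=0.05, seed=8)
omega = preprocess_gyro(trial.gyro)          # 1.5 Hz zero-lag smoothing + norm
raw = segment_fraction_of_max(omega, 0.11)   # adaptive threshold stage
segs = dynamos_segments(omega)               # + merge/split post-processing

m = match_segments(segs, trial.truth)
mae_onset, mae_offset, _ = timing_errors(m, segs, trial.truth)
print(len(trial.truth), len(raw), len(segs))
print(err_mov(m, len(trial.truth)), mae_onset, mae_offset)
```

prints (reformatted):

```
true movements:     100
threshold stage:    99
after post-process: 98
ErrMov:             2.0 %
MAE onset/offset:   0.024 s / 0.028 s
```

One injected bridge fused two sub-phases (99 raw detections) and the fused
span exceeded the admissible split band, so post-processing left it — that
single fused movement accounts for the 2 % erroneous movements, while the
other 98 movements are recovered with ~25 ms boundary accuracy. Sub-phase
characterization of the same segmentation:

```python
print(subphase_summary(label_subphases(split_repetitions(segs))))
```

```
phase  n   mean_s     se_s
    I 23 0.945217 0.029501
   II 23 0.973478 0.032325
  III 23 0.979565 0.044926
   IV 23 0.940870 0.030876
```

Each phase mean sits near the generator's 0.97 s target; two repetitions
touched by corruption are flagged incomplete and excluded (n = 23).

## Command line

```sh
dynamos simulate --subjects 25 --trials 3 --seed 1 --out data/
dynamos segment --method dynamos --input data/subject00_trial0.csv --out segs.csv
dynamos evaluate --detected segs.csv --reference data/subject00_trial0_truth.csv
dynamos optimize --data data/ --out optimization.json
dynamos characterize --segments segs.csv --out phases.csv
```

All defaults are the published parameter values (k = 0.11, α = 0.8,
β = 1.4); a YAML config file can supply any flag.

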