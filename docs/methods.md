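# Methods

## Segmentation model

All IMU segmenters operate on the angular-velocity norm Ω of a tri-axial
wrist gyroscope. The raw channels are smoothed with an effective 4th-order
zero-lag Butterworth low-pass at 1.5 Hz (a 2nd-order design run
forward-backward, reflective edge padding of 3× the effective order), then
reduced per sample to Ω = √(ωx² + ωy² + ωz²). Zero-phase filtering matters
because the deliverable is event *timing*; a causal filter would bias every
onset late.

Three threshold rules are implemented:

* **M1** — fixed threshold, 0.1 rad/s. Simple, but tied to an absolute
  scale, so slow movements flood it with noise-driven transitions.
* **M2** — adaptive, 0.25·Ωmax where Ωmax is the per-trial maximum of Ω.
  Scale-free but aggressive: low-velocity sub-phases fall below it.
* **DynAMoS threshold stage** — adaptive, k·Ωmax with k = 0.11. The
  constant is the mean of per-trial Otsu optima computed on the amplitude-
  normalized norm; `otsu_fraction_from_trials` re-estimates it from any set
  of trials, the pipelines default to the published 0.11.

Strict inequality (Ω > threshold) defines movement; samples equal to the
threshold are rest. Maximal above-threshold runs become half-open
`[onset, offset)` sample intervals; 0-based indices, durations
`(offset − onset)/fs` seconds. Segments touching the recording boundary are
kept.

### Otsu on a 1-D signal

The signal is min-max normalized and histogrammed into 256 equal bins
(config-exposed; results are insensitive above ~128 bins on smooth
kinematic signals). Candidate thresholds are interior bin edges; the
returned edge maximizes the between-class variance
w₀w₁(μ₀ − μ₁)². Runs of empty bins make consecutive edges score
identically; ties resolve to the first maximizing edge (the induced
partition is identical across the tied run). A constant signal has no two
classes and is rejected.

## Duration post-processing

Given detected durations T₁…Tₙ, the median M defines the plausibility band
[αM, βM] with 0 < α < 1 < β < 2 (defaults α = 0.8, β = 1.4, the grid-search
optimum; the published grids α ∈ 0.50…0.95, β ∈ 1.05…1.50, step 0.05 are
the `grid_search` defaults). Movements outside the band are processed
iteratively:

* **Merge** (T < αM): partner is the temporally nearest neighbour (smaller
  inter-segment gap; tie → preceding). The criterion is the *sum of the two
  durations* falling inside [αM, βM] — the gap between them is not counted —
  but the stored merged segment spans first onset → second offset, so its
  realized duration includes the gap. Keeping segments contiguous intervals
  was preferred over bookkeeping virtual durations; with ≲0.5 s gaps the
  discrepancy is small and the updated statistics absorb it.
* **Split** (T > βM): candidate points are strict interior local minima of
  the smoothed Ω inside the segment (plateau minima collapse to their
  center sample). A candidate is admissible when both pieces fall inside
  the band; among admissible candidates the most balanced split (smallest
  |T_left − T_right|) wins, earliest on a tie — balanced pieces are least
  likely to re-trigger outlier handling.

Processing order is most-extreme-first, ranked by |log(T/M)| with ties
broken by earliest onset, so gross outliers are resolved while the median
is still anchored by typical movements. After every successful event all
statistics are recomputed. A failed merge/split marks that segment
processed; the mark is cleared only when a later event changes the
segment's own bounds or its neighbours, which guarantees termination (an
explicit `max_iterations` safeguard backs this up). Idempotence on the
algorithm's own output is part of the test suite.

A structural limitation worth knowing: when bridging fuses two full-length
movements, the fused span is ≈ T₁ + T₂ + gap ≈ 2M + gap, while an
admissible split requires both pieces ≤ βM, i.e. span ≤ 2βM = 2.8M.
Bridges across longer pauses are therefore unrecoverable by construction —
the method's honest failure mode, visible in the benchmark residuals.

## Gold-standard reference path

Marker trajectories are filtered at 6 Hz (2nd-order zero-lag),
differentiated by central differences (one-sided at the edges), reduced to
the speed norm |v|, smoothed at the common 1.5 Hz, normalized by the trial
maximum vmax and thresholded at 0.11·vmax. Expert manual correction of
reference segmentations is out of algorithmic scope; externally edited
segment CSVs are accepted instead.

## Evaluation

Detected and reference movements are paired one-to-one by greedy maximal
temporal overlap; any positive overlap qualifies (overlap is parameter-free
and symmetric; an onset-distance rule would need an arbitrary window).
From the pairing:

* ErrMov = 100 · (extra + missing) / reference count (%);
* MAEOnset / MAEOffset = mean absolute boundary errors over matched pairs (s);
* duration error per pair = |T_det − T_ref|, pooled mean;
* Fc = Extra/Total + Missing/Total + mean|Δonset| + mean|Δoffset| +
  mean|ΔT|, with Extra/Missing pooled over trials and Total the total
  detected count. The cost mixes unitless rates with seconds and is
  implemented literally, without re-weighting (optional weights exist,
  default 1); a `signed` flag switches the timing terms to signed means.

Grid-search ties resolve to the smallest α, then smallest β.

## Synthetic data generator

The generator emulates the acquisition protocol: 30 s static lead
(optionally followed by a 2 s synchronization burst of rapid forearm-axis
rotations at 8 rad/s and a second static window), then 25 repetitions of
the 4-sub-phase drinking task. Per sub-phase: a raised-cosine
angular-velocity burst along a random unit direction with peak drawn from
U(1.5, 4.0) rad/s; target durations drawn from N(0.97 s, 0.15 s)
(symmetrically clipped at ±0.5 s, preserving the mean); intra-phase pauses
U(0.4, 1.2) s; 4 s rests between repetitions. White noise (sd 0.02 rad/s
per channel) and a slow sinusoidal drift (0.01 rad/s, 60 s period) are
added. The matching linear-velocity norm is the clean burst norm scaled by
150 mm per rad — a wrist lever-arm analog — and plays the
stereophotogrammetric role.

**Ground-truth convention.** The reference procedure this generator
emulates is itself a velocity-threshold segmentation, so truth is defined
as the crossings of the *noise-free* smoothed norm with 0.11 × its
maximum — not the motor-command support bounds. Burst supports are
calibrated numerically (Newton refinement against the actual smoothing
filter, alternated twice with threshold re-estimation) so that each
movement's crossing-to-crossing duration equals its drawn duration. Two
consequences: truth durations average exactly the configured 0.97 s, and
detection errors on clean signals vanish, so measured errors isolate the
effects of noise, drift and injected corruption. The default trial keeps
the synchronization burst off so that Ωmax is a task burst; with it on,
segmentation should be restricted to the task window.

**Corruption injection.** Brief dips or blips written into the raw signal
would be erased by the 1.5 Hz smoothing, so corruptions are modelled at
kinematic scale:

* *Fragmentation* re-executes a movement as two full-peak sub-movements
  separated by a 0.45 s hesitation; each piece's support is calibrated so
  its detected duration is about half the original movement, which makes
  the pair mergeable under the sum-in-band rule. Movements shorter than
  0.6 s are not fragmented (the pieces would fall below the detection
  threshold).
* *Bridging* fills an intra-repetition pause (≤ 0.7 s; sustained
  involuntary motion cannot plausibly span a 4 s rest) with a two-lobed
  bump at 0.8× the neighbouring peaks, each lobe continuing its burst's
  rotation direction so channel-wise smoothing cannot cancel it; the lobes
  overlap slightly mid-pause so the fused movement keeps an interior local
  minimum — the split point the post-processing needs.

Ground truth is never modified by corruption.

**Benchmark.** 25 subjects × 3 trials. Subject random effects: phase-
duration mean shifted by N(0, 0.1 s), peak range scaled by U(0.85, 1.15).
Seeding: one `numpy` generator per trial, trial seeds drawn from a parent
stream derived from the base seed; identical seeds give bitwise-identical
trials.

**What the generator does not emulate:** involuntary non-task movements,
gravity leakage and orientation error, sensor dropouts, asymmetric or
multi-peaked velocity profiles, and pathological movement variability.
Passing benchmarks therefore demonstrate the mechanics of thresholding and
duration repair under controlled corruption, not clinical performance on
recorded data.

## Numerical choices and degenerate inputs

* fs inferred from the median time step of a CSV; values within 0.1 % of an
  integer snap to it so that streams written at rounded timestamps compare
  equal. Streams at different rates are linearly resampled before
  cross-correlation synchronization; the lag search uses biased normalized
  correlation with ties broken by smallest |lag|.
* Filtering requires cutoff < Nyquist and signal length > 3× the effective
  order; constant inputs to the lag search, all-zero norms, and empty
  duration lists raise informative errors rather than degrade silently.
* Repetition splitting uses a 2.0 s gap threshold — between the ~1 s
  intra-task pauses and the 4 s rests; sub-phase identity is assigned by
  temporal order within a complete repetition, and incomplete repetitions
  are flagged rather than guessed. A single observation reports SE = 0
  with `se_defined = False`.

## Problem sizes

The default test and reproduction runs use the full 75-trial benchmark
(≈ 7,500 movements, ~5 min of signal per trial at 100 Hz) for error-rate
checks, a 10-trial subset for the 10 × 10 α/β grid search, and 1,000
randomized segment lists for termination checks.
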