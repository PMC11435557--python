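"""Protocol-faithful synthetic wrist-IMU drinking-task trials with exact ground truth.

A trial emulates the acquisition protocol: a 30 s static lead (optionally
followed by a synchronization burst and a second static window), then 25
repetitions of the four-sub-phase drinking task with short pauses between
sub-phases and 4 s rests between repetitions. Each sub-phase is a smooth
raised-cosine angular-velocity burst distributed over the three gyroscope
axes along a random unit direction, on top of white sensor noise and a slow
sinusoidal drift. A matching noise-free linear-velocity norm (mm/s) plays
the stereophotogrammetric part.

Ground-truth convention
-----------------------
Movement onsets/offsets follow the gold-standard convention of the source
protocol: the reference segmentation is itself a velocity-threshold
procedure, so truth is defined as the crossings of the *clean, noise-free*
smoothed norm with the adaptive threshold ``gs_fraction × Ωmax`` (default
0.11 of the trial maximum), not the motor-command support bounds. Burst
support is calibrated numerically so that the crossing-to-crossing duration
equals the drawn phase duration, so truth durations have the configured
mean (default 0.97 s) and detection errors measure only noise, drift and
injected corruption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from scipy.signal import butter, filtfilt

from .signal_core import TimeSeries, TriaxialSignal
from .sp_reference import VelocityNorm
from .threshold_segmentation import SegmentList, mask_to_segments

__all__ = [
    "TrialSpec",
    "SyntheticTrial",
    "Burst",
    "generate_trial",
    "inject_corruptions",
    "generate_benchmark",
]

#: mm of wrist linear velocity per rad/s of forearm angular velocity
VELOCITY_SCALE_MM_PER_RAD = 150.0
SYNC_PEAK_RAD_S = 8.0
SYNC_DURATION_S = 2.0
HESITATION_GAP_S = 0.45
MIN_FRAGMENT_DURATION_S = 0.6  # only movements this long can visibly hesitate
BRIDGE_LEVEL = 0.8
BRIDGE_TAIL_S = 0.3
BRIDGE_OVERLAP_S = 0.15
MAX_BRIDGE_PAUSE_S = 0.7  # sustained motion only bridges short pauses
#: smoothing applied by the segmentation pipeline; truth uses the same filter
SMOOTH_CUTOFF_HZ = 1.5
SMOOTH_ORDER = 4


@dataclass(frozen=True)
class TrialSpec:
    """Generator parameters; defaults reproduce the acquisition protocol."""

    n_reps: int = 25
    phase_duration_mean: float = 0.97  # s, crossing-to-crossing
    phase_duration_sd: float = 0.15  # s
    intra_pause: tuple[float, float] = (0.4, 1.2)  # s, between sub-phases
    rest_between_reps: float = 4.0  # s
    static_lead: float = 30.0  # s
    include_sync_burst: bool = False
    peak_omega: tuple[float, float] = (1.5, 4.0)  # rad/s
    noise_sd: float = 0.02  # rad/s per channel
    drift_amplitude: float = 0.01  # rad/s
    fs: float = 100.0
    gs_fraction: float = 0.11  # gold-standard crossing fraction of Ωmax

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("phase_duration_mean", "rest_between_reps", "static_lead", "fs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be non-negative")
        if not 0 < self.intra_pause[0] <= self.intra_pause[1]:
            raise ValueError("intra_pause range must be positive and ordered")
        if not 0 < self.peak_omega[0] <= self.peak_omega[1]:
            raise ValueError("peak_omega range must be positive and ordered")
        if not 0 < self.gs_fraction < 1:
            raise ValueError("gs_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Burst:
    """One sub-phase burst: raised-cosine support and its kinematic parameters."""

    start_s: float
    support_s: float
    peak: float
    direction: tuple[float, float, float]
    repetition: int
    phase: int  # 0..3
    duration_s: float = 0.0  # target crossing-to-crossing duration


@dataclass(frozen=True)
class SyntheticTrial:
    gyro: TriaxialSignal
    linear_velocity: VelocityNorm
    truth: SegmentList
    spec: TrialSpec
    bursts: tuple[Burst, ...] = ()
    corruption_log: tuple[str, ...] = ()
    truth_threshold: float = 0.0  # gs_fraction x smoothed clean norm maximum

    @property
    def fs(self) -> float:
        return self.spec.fs


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine profile over n samples (zero at both ends)."""
    t = np.arange(n) / max(n - 1, 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _add_burst(channels: np.ndarray, start_s: float, support_s: float, peak: float,
               direction: np.ndarray, fs: float, sign: float = 1.0) -> None:
    i0 = int(round(start_s * fs))
    n = int(round(support_s * fs))
    profile = peak * _raised_cosine(n)
    channels[i0 : i0 + n] += sign * np.outer(profile, direction)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """The pipeline's zero-lag smoothing (effective 4th order at 1.5 Hz)."""
    b, a = butter(SMOOTH_ORDER // 2, SMOOTH_CUTOFF_HZ / (fs / 2.0))
    return filtfilt(b, a, x, padtype="even", padlen=3 * SMOOTH_ORDER)


def _isolated_burst_smoothed(peak: float, support: float, fs: float) -> np.ndarray:
    n = int(round(support * fs))
    x = np.zeros(n + 600)
    x[300 : 300 + n] = peak * _raised_cosine(n)
    return _smooth(x, fs)


def _crossing_duration(peak: float, support: float, th: float, fs: float) -> float:
    sm = _isolated_burst_smoothed(peak, support, fs)
    above = np.flatnonzero(sm > th)
    if above.size == 0:
        return 0.0
    return (above[-1] + 1 - above[0]) / fs


def _calibrate_supports(
    durs: np.ndarray, peaks: np.ndarray, fraction: float, fs: float
) -> tuple[np.ndarray, float]:
    """Support lengths whose *smoothed* threshold-crossing duration equals ``durs``.

    The threshold is ``fraction`` times the maximum of the smoothed norm, which
    itself depends on the supports, so threshold and supports are refined
    alternately (two rounds suffice: the smoothed peak moves by < 1% per round).
    """
    th = fraction * float(peaks.max())  # unsmoothed initialization
    u = np.arccos(1.0 - 2.0 * np.minimum(th / peaks, 0.999)) / (2.0 * np.pi)
    supports = durs / (1.0 - 2.0 * u)
    for _ in range(2):
        smoothed_peaks = [
            _isolated_burst_smoothed(p, s, fs).max() for p, s in zip(peaks, supports)
        ]
        th = fraction * float(np.max(smoothed_peaks))
        u = np.arccos(1.0 - 2.0 * np.minimum(th / peaks, 0.999)) / (2.0 * np.pi)
        slope = 1.0 - 2.0 * u  # d(crossing duration)/d(support), pre-smoothing
        for i in range(durs.size):
            for _ in range(4):
                err = durs[i] - _crossing_duration(peaks[i], supports[i], th, fs)
                if abs(err) <= 0.5 / fs:
                    break
                supports[i] = max(supports[i] + err / slope[i], 0.2)
    return supports, th


def generate_trial(spec: TrialSpec | None = None, seed: int = 0) -> SyntheticTrial:
    """Generate one trial with exact ground truth.

    The same (spec, seed) pair always yields a bitwise-identical trial.
    """
    spec = spec or TrialSpec()
    rng = np.random.default_rng(seed)
    fs = spec.fs
    n_bursts = 4 * spec.n_reps

    # kinematic draws; symmetric clipping keeps the duration mean exact
    durs = rng.normal(spec.phase_duration_mean, spec.phase_duration_sd, n_bursts)
    durs = np.clip(durs, spec.phase_duration_mean - 0.5, spec.phase_duration_mean + 0.5)
    durs = np.maximum(durs, 0.3)
    peaks = rng.uniform(*spec.peak_omega, n_bursts)
    directions = np.stack([_unit_vector(rng) for _ in range(n_bursts)])
    supports, th = _calibrate_supports(durs, peaks, spec.gs_fraction, fs)

    # timeline
    cursor = spec.static_lead
    sync_span = None
    if spec.include_sync_burst:
        sync_span = (cursor, cursor + SYNC_DURATION_S)
        cursor += SYNC_DURATION_S + spec.static_lead
    bursts: list[Burst] = []
    k = 0
    for rep in range(spec.n_reps):
        for phase in range(4):
            bursts.append(
                Burst(
                    start_s=cursor,
                    support_s=float(supports[k]),
                    peak=float(peaks[k]),
                    direction=tuple(directions[k]),
                    repetition=rep,
                    phase=phase,
                    duration_s=float(durs[k]),
                )
            )
            cursor += supports[k]
            if phase < 3:
                cursor += rng.uniform(*spec.intra_pause)
            k += 1
        if rep < spec.n_reps - 1:
            cursor += spec.rest_between_reps
    total_s = cursor + 2.0
    n = int(np.ceil(total_s * fs))

    # clean task signal; truth = the segmentation pipeline on the noise-free signal
    channels = np.zeros((n, 3))
    for b in bursts:
        _add_burst(channels, b.start_s, b.support_s, b.peak, np.asarray(b.direction), fs)
    clean_norm = np.linalg.norm(channels, axis=1)
    smoothed_clean = np.linalg.norm(
        np.column_stack([_smooth(channels[:, c], fs) for c in range(3)]), axis=1
    )
    th_trial = spec.gs_fraction * float(smoothed_clean.max())
    truth = mask_to_segments(smoothed_clean > th_trial, fs)
    if len(truth) != n_bursts:  # pragma: no cover - generator self-check
        raise RuntimeError("ground-truth segment count does not match burst count")

    # optional synchronization movement (rapid forearm-axis rotations)
    if sync_span is not None:
        i0, i1 = int(sync_span[0] * fs), int(sync_span[1] * fs)
        t = np.arange(i1 - i0) / fs
        envelope = _raised_cosine(i1 - i0)
        channels[i0:i1, 0] += SYNC_PEAK_RAD_S * envelope * np.sin(2 * np.pi * 3.0 * t)

    # sensor imperfections
    if spec.noise_sd > 0:
        channels = channels + rng.normal(0.0, spec.noise_sd, channels.shape)
    if spec.drift_amplitude > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, 3)
        drift = spec.drift_amplitude * np.sin(2 * np.pi * t[:, None] / 60.0 + phases)
        channels = channels + drift

    gyro = TriaxialSignal(channels[:, 0], channels[:, 1], channels[:, 2], fs=fs)
    lv = VelocityNorm.from_series(
        TimeSeries(VELOCITY_SCALE_MM_PER_RAD * clean_norm, fs=fs)
    )
    return SyntheticTrial(
        gyro=gyro,
        linear_velocity=lv,
        truth=truth,
        spec=spec,
        bursts=tuple(bursts),
        truth_threshold=th_trial,
    )


def inject_corruptions(
    trial: SyntheticTrial,
    fragmentation_rate: float = 0.05,
    bridging_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticTrial:
    """Inject segmentation-hostile events into the gyroscope signal.

    Fragmentation re-executes a randomly chosen movement as two full-peak
    sub-movements separated by a ~0.45 s hesitation; the sub-movement
    supports are calibrated so that each detected piece lasts about half the
    original movement, so raw thresholding sees two short movements where
    the ground truth has one. Bridging adds a sustained raised-cosine motion
    bump across a short intra-repetition pause (overlapping the neighbouring
    burst tails), so raw thresholding fuses two movements into one. Brief
    dips or blips would be erased by the mandatory 1.5 Hz smoothing, hence
    the kinematic-scale events. The bridging bump has two lobes (one per
    junction) whose smoothed norm dips mid-pause while staying above the
    threshold, so the fused movement keeps an interior local minimum — the
    split point the post-processing needs. The ground truth is left
    unchanged.
    """
    if not 0 <= fragmentation_rate <= 1 or not 0 <= bridging_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fs = trial.spec.fs
    th = trial.truth_threshold
    channels = trial.gyro.as_matrix().copy()
    log: list[str] = list(trial.corruption_log)

    for k, b in enumerate(trial.bursts):
        if b.duration_s < MIN_FRAGMENT_DURATION_S:
            continue
        if rng.random() >= fragmentation_rate:
            continue
        piece = _piece_support(b.peak, b.duration_s / 2.0, th, fs)
        if piece is None:
            continue  # sub-movement would fall below the detection threshold
        direction = np.asarray(b.direction)
        _add_burst(channels, b.start_s, b.support_s, b.peak, direction, fs, sign=-1.0)
        center = b.start_s + b.support_s / 2.0
        _add_burst(channels, center - HESITATION_GAP_S / 2.0 - piece, piece, b.peak, direction, fs)
        _add_burst(channels, center + HESITATION_GAP_S / 2.0, piece, b.peak, direction, fs)
        log.append(f"fragment burst {k} at {b.start_s:.2f}s")

    for k in range(len(trial.bursts) - 1):
        left, right = trial.bursts[k], trial.bursts[k + 1]
        if left.repetition != right.repetition:
            continue  # only intra-repetition pauses are bridged
        pause = right.start_s - (left.start_s + left.support_s)
        if pause > MAX_BRIDGE_PAUSE_S:
            continue  # sustained involuntary motion cannot span a long pause
        if rng.random() >= bridging_rate:
            continue
        # one lobe per junction, each continuing its burst's rotation so that
        # channel-wise smoothing cannot cancel it; the lobes overlap slightly
        # so the norm dips mid-pause but stays above the threshold
        mid = left.start_s + left.support_s + pause / 2.0
        lobe_start = left.start_s + left.support_s - BRIDGE_TAIL_S
        _add_burst(channels, lobe_start, mid + BRIDGE_OVERLAP_S - lobe_start,
                   BRIDGE_LEVEL * left.peak, np.asarray(left.direction), fs)
        _add_burst(channels, mid - BRIDGE_OVERLAP_S,
                   right.start_s + BRIDGE_TAIL_S - (mid - BRIDGE_OVERLAP_S),
                   BRIDGE_LEVEL * right.peak, np.asarray(right.direction), fs)
        log.append(f"bridge pause after burst {k} at {left.start_s + left.support_s:.2f}s")

    gyro = TriaxialSignal(channels[:, 0], channels[:, 1], channels[:, 2], fs=fs)
    return replace(trial, gyro=gyro, corruption_log=tuple(log))


def _piece_support(peak: float, target_duration: float, th: float, fs: float) -> float | None:
    """Support of a full-peak sub-burst whose detected duration hits the target.

    Returns None when no support keeps the smoothed sub-burst both above the
    threshold and short enough (narrow pulses are strongly attenuated by the
    1.5 Hz smoothing).
    """
    support = max(target_duration, 0.2)
    for _ in range(6):
        got = _crossing_duration(peak, support, th, fs)
        if got == 0.0:
            support *= 1.5
            continue
        err = target_duration - got
        if abs(err) <= 1.0 / fs:
            return support
        support = max(support + 0.8 * err, 0.1)
    got = _crossing_duration(peak, support, th, fs)
    if got == 0.0 or abs(got - target_duration) > 0.15:
        return None
    return support


def generate_benchmark(
    n_subjects: int = 25,
    n_trials_per_subject: int = 3,
    base_seed: int = 0,
    spec: TrialSpec | None = None,
    fragmentation_rate: float = 0.0,
    bridging_rate: float = 0.0,
    subject_duration_sd: float = 0.1,
    subject_peak_scale_range: tuple[float, float] = (0.85, 1.15),
    out_dir: str | Path | None = None,
):
    """Generate the full multi-subject benchmark (default 25 × 3 = 75 trials).

    Each subject receives random effects on the phase-duration mean and on
    the peak angular-velocity range. Returns a list of
    ``(subject, trial_index, SyntheticTrial)``; with ``out_dir`` the trials,
    ground truth and a manifest are also written as CSV/JSON.
    """
    if n_subjects < 1 or n_trials_per_subject < 1:
        raise ValueError("counts must be >= 1")
    base = spec or TrialSpec()
    parent = np.random.default_rng(base_seed)
    dataset = []
    for s in range(n_subjects):
        subj_mean = base.phase_duration_mean + parent.normal(0.0, subject_duration_sd)
        subj_mean = float(np.clip(subj_mean, 0.5, 1.5))
        scale = parent.uniform(*subject_peak_scale_range)
        subj_spec = replace(
            base,
            phase_duration_mean=subj_mean,
            peak_omega=(base.peak_omega[0] * scale, base.peak_omega[1] * scale),
        )
        for t in range(n_trials_per_subject):
            seed = int(parent.integers(2**31))
            trial = generate_trial(subj_spec, seed)
            if fragmentation_rate > 0 or bridging_rate > 0:
                trial = inject_corruptions(
                    trial, fragmentation_rate, bridging_rate, seed=int(parent.integers(2**31))
                )
            dataset.append((s, t, trial))
    if out_dir is not None:
        write_benchmark(dataset, out_dir, base_seed)
    return dataset


def write_trial_csv(trial: SyntheticTrial, path: str | Path) -> None:
    """Write the gyroscope channels in the IMU trial CSV dialect."""
    t = np.arange(len(trial.gyro)) / trial.fs
    pd.DataFrame(
        {
            "time_s": np.round(t, 4),
            "gyro_x_rad_s": trial.gyro.x,
            "gyro_y_rad_s": trial.gyro.y,
            "gyro_z_rad_s": trial.gyro.z,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_segments_csv(segs: SegmentList, path: str | Path, trial_id: str = "trial") -> None:
    rows = [
        {
            "trial_id": trial_id,
            "segment_index": i,
            "onset_s": round(a / segs.fs, 4),
            "offset_s": round(b / segs.fs, 4),
            "onset_sample": a,
            "offset_sample": b,
        }
        for i, (a, b) in enumerate(segs)
    ]
    pd.DataFrame(
        rows,
        columns=["trial_id", "segment_index", "onset_s", "offset_s", "onset_sample", "offset_sample"],
    ).to_csv(path, index=False)


def read_segments_csv(path: str | Path, fs: float) -> SegmentList:
    df = pd.read_csv(path)
    segs = tuple(zip(df["onset_sample"].astype(int), df["offset_sample"].astype(int)))
    return SegmentList(segs, fs=fs)


def write_benchmark(dataset, out_dir: str | Path, base_seed: int) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"base_seed": base_seed, "trials": []}
    for s, t, trial in dataset:
        stem = f"subject{s:02d}_trial{t}"
        write_trial_csv(trial, out / f"{stem}.csv")
        write_segments_csv(trial.truth, out / f"{stem}_truth.csv", trial_id=stem)
        manifest["trials"].append(
            {
                "trial_id": stem,
                "imu_csv": f"{stem}.csv",
                "truth_csv": f"{stem}_truth.csv",
                "fs": trial.fs,
                "n_truth": len(trial.truth),
                "corruptions": list(trial.corruption_log),
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
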