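"""Otsu threshold selection, mask/segment conversion, and the threshold segmenters.

Three segmenters operate on the angular-velocity norm Ω:

* M1 — fixed threshold, 0.1 rad/s.
* M2 — adaptive threshold at 0.25·Ωmax.
* The adaptive stage of DynAMoS — k·Ωmax with k = 0.11, where k was chosen
  as the average of per-trial Otsu optima on the normalized norm.

Samples strictly above the threshold are voluntary movement; maximal runs of
such samples become half-open ``[onset, offset)`` segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import TimeSeries

__all__ = [
    "SegmentList",
    "ThresholdConfig",
    "otsu_threshold",
    "mask_to_segments",
    "segments_to_mask",
    "segment_fixed",
    "segment_fraction_of_max",
    "otsu_fraction_from_trials",
]


@dataclass(frozen=True)
class SegmentList:
    """Ordered, non-overlapping half-open ``[onset, offset)`` sample intervals."""

    segments: tuple[tuple[int, int], ...]
    fs: float

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        prev_end = 0
        for a, b in segs:
            if a < 0 or b <= a:
                raise ValueError(f"invalid segment ({a}, {b})")
            if a < prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = b
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "segments", segs)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def durations(self) -> np.ndarray:
        """Per-segment durations in seconds."""
        arr = np.asarray(self.segments, dtype=float).reshape(-1, 2)
        return (arr[:, 1] - arr[:, 0]) / self.fs

    def onsets_s(self) -> np.ndarray:
        return np.asarray([a for a, _ in self.segments], float) / self.fs

    def offsets_s(self) -> np.ndarray:
        return np.asarray([b for _, b in self.segments], float) / self.fs


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold-method selection and its published default parameters."""

    method: str = "dynamos"  # m1 | m2 | dynamos | sp
    fixed_value: float = 0.1  # rad/s, M1
    fraction: float = 0.11  # k for dynamos/sp; 0.25 for m2
    otsu_bins: int = 256

    def __post_init__(self) -> None:
        if self.method not in ("m1", "m2", "dynamos", "sp"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "m1" and not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if self.fixed_value <= 0:
            raise ValueError("fixed_value must be positive")


def otsu_threshold(ts: TimeSeries, n_bins: int = 256) -> float:
    """Otsu's between-class-variance-maximizing threshold on a 1-D signal.

    The signal is min-max normalized to [0, 1] and histogrammed into
    ``n_bins`` equal-width bins; the returned threshold is the interior bin
    edge maximizing the between-class variance, on the normalized scale.
    Distinguishes the low-amplitude "background" (rest, noise) from the
    high-amplitude movement class.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = ts.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("degenerate histogram: constant signal has no two classes")
    norm = (v - lo) / (hi - lo)
    counts, edges = np.histogram(norm, bins=n_bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    # cumulative class probability and class mean numerator at each interior edge
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]  # mass at or below edge k (bins 0..k)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    mu0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * (1.0 - w0))
    sigma_b = np.where((w0 > 0) & (w0 < 1), sigma_b, -np.inf)
    if not np.any(np.isfinite(sigma_b)):
        raise ValueError("degenerate histogram: all mass in a single bin")
    best = int(np.argmax(sigma_b))
    return float(edges[best + 1])


def mask_to_segments(mask: np.ndarray, fs: float) -> SegmentList:
    """Maximal runs of True become half-open segments."""
    m = np.asarray(mask, dtype=bool)
    if m.size < 1:
        raise ValueError("mask must have at least one sample")
    padded = np.concatenate([[False], m, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return SegmentList(tuple(zip(starts.tolist(), ends.tolist())), fs=fs)


def segments_to_mask(segs: SegmentList, n_samples: int) -> np.ndarray:
    """Inverse of :func:`mask_to_segments` for a known signal length."""
    mask = np.zeros(n_samples, dtype=bool)
    for a, b in segs:
        if b > n_samples:
            raise ValueError("segment exceeds signal length")
        mask[a:b] = True
    return mask


def segment_fixed(omega: TimeSeries, threshold: float = 0.1) -> SegmentList:
    """M1: fixed threshold (default 0.1 rad/s) on the angular-velocity norm."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return mask_to_segments(omega.values > threshold, omega.fs)


def segment_fraction_of_max(omega: TimeSeries, fraction: float) -> SegmentList:
    """Adaptive threshold at ``fraction × max(Ω)`` over the trial.

    Serves both M2 (fraction 0.25) and the DynAMoS threshold stage
    (fraction k = 0.11).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    peak = float(omega.values.max())
    if peak <= 0:
        raise ValueError("signal maximum must be positive (all-zero signal)")
    return mask_to_segments(omega.values > fraction * peak, omega.fs)


def otsu_fraction_from_trials(trials, n_bins: int = 256) -> float:
    """Recompute the adaptive fraction k as the mean of per-trial Otsu optima.

    This is how the published k = 0.11 was derived; the default pipelines use
    the published constant, and this opt-in path re-estimates it from a set
    of norm TimeSeries.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    return float(np.mean([otsu_threshold(t, n_bins) for t in trials]))
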