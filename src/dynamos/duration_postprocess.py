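"""Statistics-based iterative merge/split post-processing on movement durations.

Thresholding a fluctuating norm produces duration outliers: fragmented
movements (too short) and bridged movements (too long). This stage computes
the median movement duration M and flags segments outside [αM, βM]
(0 < α < 1 < β < 2; published optimum α = 0.8, β = 1.4). Short outliers are
merged with their temporally nearest neighbour when the summed duration
falls inside the band; long outliers are split at an interior local minimum
of Ω when both pieces fall inside the band. After every successful event the
duration statistics are updated, and the loop runs until every outlier has
been processed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_core import TimeSeries
from .threshold_segmentation import SegmentList

__all__ = [
    "PostprocessConfig",
    "DurationStats",
    "durations",
    "duration_stats",
    "try_merge",
    "try_split",
    "postprocess",
]


@dataclass(frozen=True)
class PostprocessConfig:
    alpha: float = 0.8
    beta: float = 1.4
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 1 < self.beta < 2:
            raise ValueError("beta must lie in (1, 2)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass(frozen=True)
class DurationStats:
    """Median duration M and the αM / βM outlier band (seconds)."""

    median: float
    lower: float
    upper: float


def durations(segs: SegmentList) -> list[float]:
    """Per-movement durations T_i = (offset_i − onset_i) / fs, seconds."""
    return segs.durations().tolist()


def duration_stats(ds, cfg: PostprocessConfig) -> DurationStats:
    """Median of the duration distribution and its αM/βM band."""
    ds = list(ds)
    if not ds:
        raise ValueError("need at least one duration")
    m = float(np.median(ds))
    return DurationStats(median=m, lower=cfg.alpha * m, upper=cfg.beta * m)


def _nearest_neighbor(segs: SegmentList, i: int) -> int | None:
    """Neighbour with the smaller inter-segment gap; tie -> preceding."""
    left = i - 1 if i > 0 else None
    right = i + 1 if i < len(segs) - 1 else None
    if left is None and right is None:
        return None
    if right is None:
        return left
    if left is None:
        return right
    gap_left = segs[i][0] - segs[left][1]
    gap_right = segs[right][0] - segs[i][1]
    return left if gap_left <= gap_right else right


def try_merge(
    segs: SegmentList, i: int, omega: TimeSeries, stats: DurationStats
) -> tuple[SegmentList, bool]:
    """Attempt to merge short-outlier segment ``i`` with its nearest neighbour.

    The merge criterion is the *sum of the two movement durations* (the gap
    between them is not counted); the stored merged segment nevertheless
    spans from the first onset to the second offset, so its realized
    duration includes the gap.
    """
    if not 0 <= i < len(segs):
        raise IndexError("segment index out of range")
    durs = segs.durations()
    if not durs[i] < stats.lower:
        raise ValueError("segment is not a short-duration outlier")
    j = _nearest_neighbor(segs, i)
    if j is None:
        return segs, False
    if not stats.lower <= durs[i] + durs[j] <= stats.upper:
        return segs, False
    lo, hi = min(i, j), max(i, j)
    merged = (segs[lo][0], segs[hi][1])
    new = segs.segments[:lo] + (merged,) + segs.segments[hi + 1 :]
    return SegmentList(new, fs=segs.fs), True


def _interior_local_minima(values: np.ndarray, onset: int, offset: int) -> list[int]:
    """Strict interior local minima of ``values`` within (onset, offset).

    Plateau minima (flat valleys) collapse to their center sample.
    """
    seg = values[onset:offset]
    n = seg.size
    minima: list[int] = []
    k = 1
    while k < n - 1:
        if seg[k] < seg[k - 1]:
            # scan a potential plateau [k, j]
            j = k
            while j + 1 < n and seg[j + 1] == seg[k]:
                j += 1
            if j < n - 1 and seg[j + 1] > seg[k]:
                minima.append(onset + (k + j) // 2)
            k = j + 1
        else:
            k += 1
    return minima


def try_split(
    segs: SegmentList, i: int, omega: TimeSeries, stats: DurationStats
) -> tuple[SegmentList, bool]:
    """Attempt to split long-outlier segment ``i`` at a local minimum of Ω.

    Candidate split points are interior local minima of the norm inside the
    segment; a candidate is admissible when both resulting durations fall
    inside [αM, βM]. Among admissible candidates the most balanced split
    (smallest |T_left − T_right|) wins, earliest on a tie.
    """
    if not 0 <= i < len(segs):
        raise IndexError("segment index out of range")
    onset, offset = segs[i]
    if not (offset - onset) / segs.fs > stats.upper:
        raise ValueError("segment is not a long-duration outlier")
    best: tuple[float, int] | None = None
    for s in _interior_local_minima(omega.values, onset, offset):
        t_left = (s - onset) / segs.fs
        t_right = (offset - s) / segs.fs
        if stats.lower <= t_left <= stats.upper and stats.lower <= t_right <= stats.upper:
            key = (abs(t_left - t_right), s)
            if best is None or key < best:
                best = key
    if best is None:
        return segs, False
    s = best[1]
    new = segs.segments[:i] + ((onset, s), (s, offset)) + segs.segments[i + 1 :]
    return SegmentList(new, fs=segs.fs), True


def postprocess(
    segs: SegmentList, omega: TimeSeries, cfg: PostprocessConfig | None = None
) -> SegmentList:
    """Iterate merge/split until every duration outlier has been processed.

    Outliers are handled most-extreme-first (largest \\|log(T/M)\\|, ties by
    earliest onset). A failed merge/split marks the segment processed; the
    mark is cleared if a later event changes the segment's neighbourhood.
    Statistics are recomputed over all current segments after every
    successful event.
    """
    cfg = cfg or PostprocessConfig()
    if len(segs) == 0:
        return segs
    processed: set[tuple[int, int, int | None, int | None]] = set()

    def key_of(cur: SegmentList, idx: int):
        left = cur[idx - 1] if idx > 0 else None
        right = cur[idx + 1] if idx < len(cur) - 1 else None
        return (*cur[idx], left, right)

    for _ in range(cfg.max_iterations):
        durs = segs.durations()
        stats = duration_stats(durs, cfg)
        candidates = []
        for idx, t in enumerate(durs):
            if (t < stats.lower or t > stats.upper) and key_of(segs, idx) not in processed:
                candidates.append((-abs(math.log(t / stats.median)), segs[idx][0], idx))
        if not candidates:
            return segs
        candidates.sort()
        idx = candidates[0][2]
        if durs[idx] < stats.lower:
            new_segs, ok = try_merge(segs, idx, omega, stats)
        else:
            new_segs, ok = try_split(segs, idx, omega, stats)
        if ok:
            segs = new_segs
        else:
            processed.add(key_of(segs, idx))
    raise RuntimeError("postprocess failed to terminate within max_iterations")
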