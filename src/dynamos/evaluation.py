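"""Movement matching, performance metrics, the cost function and the α/β grid search.

Detected movements are paired one-to-one with reference movements by greedy
maximal temporal overlap. From the pairing come the per-trial metrics
(Nmov, ErrMov, MAEOnset, MAEOffset, mean duration) and the pooled cost

    Fc = Extra/Total + Missing/Total + mean|Δonset| + mean|Δoffset| + mean|ΔT|

where Extra and Missing are counted over all trials, Total is the total
number of detected movements, and the timing terms are pooled means in
seconds over matched pairs. The α/β post-processing parameters are chosen by
minimizing Fc over a grid (published grids α ∈ 0.50…0.95, β ∈ 1.05…1.50,
step 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duration_postprocess import PostprocessConfig, postprocess
from .signal_core import TimeSeries
from .threshold_segmentation import SegmentList, segment_fraction_of_max

__all__ = [
    "MatchResult",
    "CostBreakdown",
    "match_segments",
    "err_mov",
    "timing_errors",
    "cost_function",
    "grid_search",
    "ALPHA_GRID",
    "BETA_GRID",
]

ALPHA_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))
BETA_GRID = tuple(np.round(np.arange(1.05, 1.501, 0.05), 2))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of detected and reference movements."""

    pairs: tuple[tuple[int, int], ...]
    extra: tuple[int, ...]  # unmatched detected indices
    missing: tuple[int, ...]  # unmatched reference indices


@dataclass(frozen=True)
class CostBreakdown:
    extra_rate: float
    missing_rate: float
    mean_onset_err: float
    mean_offset_err: float
    mean_duration_err: float

    @property
    def fc(self) -> float:
        return (
            self.extra_rate
            + self.missing_rate
            + self.mean_onset_err
            + self.mean_offset_err
            + self.mean_duration_err
        )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def match_segments(detected: SegmentList, reference: SegmentList) -> MatchResult:
    """Greedy one-to-one matching by maximal temporal overlap.

    Only positive-overlap pairs qualify; ties are broken by earliest
    detected then reference index.
    """
    if detected.fs != reference.fs:
        raise ValueError("detected and reference must share a sampling frequency")
    scored = []
    for i, d in enumerate(detected):
        for j, r in enumerate(reference):
            if r[0] >= d[1]:
                break
            ov = _overlap(d, r)
            if ov > 0:
                scored.append((-ov, i, j))
    scored.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in scored:
        if i not in used_d and j not in used_r:
            pairs.append((i, j))
            used_d.add(i)
            used_r.add(j)
    pairs.sort()
    extra = tuple(i for i in range(len(detected)) if i not in used_d)
    missing = tuple(j for j in range(len(reference)) if j not in used_r)
    return MatchResult(pairs=tuple(pairs), extra=extra, missing=missing)


def err_mov(m: MatchResult, reference_count: int) -> float:
    """Percentage of erroneous movements (extra + missing) vs the reference."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return 100.0 * (len(m.extra) + len(m.missing)) / reference_count


def timing_errors(
    m: MatchResult, detected: SegmentList, reference: SegmentList
) -> tuple[float, float, float]:
    """(MAEOnset, MAEOffset, mean |ΔT|) in seconds over matched pairs."""
    if not m.pairs:
        raise ValueError("no matched pairs")
    fs = detected.fs
    d_on, d_off, d_dur = [], [], []
    for i, j in m.pairs:
        d, r = detected[i], reference[j]
        d_on.append(abs(d[0] - r[0]) / fs)
        d_off.append(abs(d[1] - r[1]) / fs)
        d_dur.append(abs((d[1] - d[0]) - (r[1] - r[0])) / fs)
    return float(np.mean(d_on)), float(np.mean(d_off)), float(np.mean(d_dur))


def cost_function(trials, signed: bool = False, weights=None) -> CostBreakdown:
    """Pooled cost over (detected, reference) SegmentList pairs.

    ``signed=False`` (default) uses absolute timing errors; ``signed=True``
    uses signed means. ``weights`` optionally rescales the five terms.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    total_detected = sum(len(d) for d, _ in trials)
    if total_detected == 0:
        raise ValueError("no detected movements in any trial")
    n_extra = n_missing = 0
    onset_errs: list[float] = []
    offset_errs: list[float] = []
    duration_errs: list[float] = []
    for detected, reference in trials:
        m = match_segments(detected, reference)
        n_extra += len(m.extra)
        n_missing += len(m.missing)
        fs = detected.fs
        for i, j in m.pairs:
            d, r = detected[i], reference[j]
            e_on = (d[0] - r[0]) / fs
            e_off = (d[1] - r[1]) / fs
            e_dur = ((d[1] - d[0]) - (r[1] - r[0])) / fs
            if not signed:
                e_on, e_off, e_dur = abs(e_on), abs(e_off), abs(e_dur)
            onset_errs.append(e_on)
            offset_errs.append(e_off)
            duration_errs.append(e_dur)
    mean = lambda xs: float(np.mean(xs)) if xs else 0.0
    terms = [
        n_extra / total_detected,
        n_missing / total_detected,
        mean(onset_errs),
        mean(offset_errs),
        mean(duration_errs),
    ]
    if weights is not None:
        terms = [w * t for w, t in zip(weights, terms)]
    return CostBreakdown(*terms)


def trial_metrics(detected: SegmentList, reference: SegmentList) -> dict:
    """Per-trial performance summary (Nmov, ErrMov, MAEs, mean duration)."""
    m = match_segments(detected, reference)
    out = {
        "n_detected": len(detected),
        "n_reference": len(reference),
        "n_extra": len(m.extra),
        "n_missing": len(m.missing),
        "err_mov_pct": err_mov(m, len(reference)),
        "mean_duration_s": float(np.mean(detected.durations())) if len(detected) else 0.0,
    }
    if m.pairs:
        mae_on, mae_off, mae_dur = timing_errors(m, detected, reference)
        out.update(mae_onset_s=mae_on, mae_offset_s=mae_off, mae_duration_s=mae_dur)
    return out


def grid_search(
    dataset,
    alpha_grid=ALPHA_GRID,
    beta_grid=BETA_GRID,
    fraction: float = 0.11,
):
    """Optimize α/β by minimizing Fc over a grid.

    ``dataset`` is an iterable of (omega: TimeSeries, reference: SegmentList)
    pairs, with omega already smoothed. The full DynAMoS pipeline (adaptive
    threshold at ``fraction``·Ωmax + post-processing) runs in every cell;
    ties go to the smallest α, then smallest β. Returns
    (alpha*, beta*, fc_surface) with the surface indexed [i_alpha, i_beta].
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    alpha_grid = list(alpha_grid)
    beta_grid = list(beta_grid)
    if not alpha_grid or not beta_grid:
        raise ValueError("empty grid")
    raw = [(segment_fraction_of_max(omega, fraction), omega, ref) for omega, ref in dataset]
    surface = np.empty((len(alpha_grid), len(beta_grid)))
    best = None
    for ia, alpha in enumerate(alpha_grid):
        for ib, beta in enumerate(beta_grid):
            cfg = PostprocessConfig(alpha=alpha, beta=beta)
            pairs = [(postprocess(segs, omega, cfg), ref) for segs, omega, ref in raw]
            fc = cost_function(pairs).fc
            surface[ia, ib] = fc
            if best is None or fc < best[0] - 1e-15:
                best = (fc, alpha, beta)
    return best[1], best[2], surface
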