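"""End-to-end segmentation pipelines tying preprocessing, thresholding and post-processing.

The common path for all IMU methods: (optional) static-bias removal, 1.5 Hz
fourth-order zero-lag smoothing of the gyroscope channels, angular-velocity
norm Ω, then the method-specific threshold; DynAMoS additionally runs the
duration merge/split post-processing.
"""

from __future__ import annotations

from .duration_postprocess import PostprocessConfig, postprocess
from .signal_core import TimeSeries, TriaxialSignal, lowpass_triaxial, remove_static_bias, vector_norm
from .threshold_segmentation import (
    SegmentList,
    segment_fixed,
    segment_fraction_of_max,
)

__all__ = ["preprocess_gyro", "segment_method", "dynamos_segments"]

SMOOTH_CUTOFF_HZ = 1.5
SMOOTH_ORDER = 4
M1_THRESHOLD_RAD_S = 0.1
M2_FRACTION = 0.25
DYNAMOS_K = 0.11


def preprocess_gyro(
    gyro: TriaxialSignal,
    cutoff: float = SMOOTH_CUTOFF_HZ,
    order: int = SMOOTH_ORDER,
    static_window: tuple[int, int] | None = None,
) -> TimeSeries:
    """Smoothed angular-velocity norm Ω from raw gyroscope channels."""
    if static_window is not None:
        gyro = remove_static_bias(gyro, static_window)
    return vector_norm(lowpass_triaxial(gyro, cutoff, order))


def segment_method(
    omega: TimeSeries,
    method: str,
    fixed_value: float = M1_THRESHOLD_RAD_S,
    fraction: float | None = None,
    post: PostprocessConfig | None = None,
) -> SegmentList:
    """Run one of the segmenters (``m1``, ``m2``, ``dynamos``) on a smoothed norm."""
    method = method.lower()
    if method == "m1":
        return segment_fixed(omega, fixed_value)
    if method == "m2":
        return segment_fraction_of_max(omega, M2_FRACTION if fraction is None else fraction)
    if method == "dynamos":
        segs = segment_fraction_of_max(omega, DYNAMOS_K if fraction is None else fraction)
        return postprocess(segs, omega, post or PostprocessConfig())
    raise ValueError(f"unknown method {method!r}")


def dynamos_segments(
    omega: TimeSeries,
    k: float = DYNAMOS_K,
    alpha: float = 0.8,
    beta: float = 1.4,
) -> SegmentList:
    """Full DynAMoS: adaptive threshold k·Ωmax plus duration post-processing."""
    cfg = PostprocessConfig(alpha=alpha, beta=beta)
    return postprocess(segment_fraction_of_max(omega, k), omega, cfg)
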