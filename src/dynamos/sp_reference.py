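"""Gold-standard segmentation from marker-derived linear velocity.

The stereophotogrammetric (SP) reference path: marker trajectories are
low-pass filtered at 6 Hz, differentiated to linear velocity, reduced to the
speed norm |v|, smoothed at 1.5 Hz, normalized by the trial maximum vmax and
thresholded at 0.11·vmax. The resulting segments (optionally expert-edited
offline) are the reference against which the IMU segmenters are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import TimeSeries, TriaxialSignal, lowpass_triaxial, lowpass_zero_lag
from .threshold_segmentation import SegmentList, mask_to_segments

__all__ = ["VelocityNorm", "linear_velocity_norm", "sp_segments", "filter_markers"]

MARKER_CUTOFF_HZ = 6.0
SMOOTH_CUTOFF_HZ = 1.5
SP_FRACTION = 0.11


@dataclass(frozen=True)
class VelocityNorm:
    """Linear-velocity norm |v| (mm/s) with its trial maximum vmax."""

    series: TimeSeries
    vmax: float

    def __post_init__(self) -> None:
        if np.any(self.series.values < 0):
            raise ValueError("velocity norm must be non-negative")
        expected = float(self.series.values.max())
        if abs(self.vmax - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("vmax must equal the series maximum")

    @classmethod
    def from_series(cls, ts: TimeSeries) -> "VelocityNorm":
        values = np.maximum(ts.values, 0.0)
        ts = TimeSeries(values, fs=ts.fs, start_time=ts.start_time)
        return cls(series=ts, vmax=float(values.max()))


def filter_markers(markers: TriaxialSignal, cutoff: float = MARKER_CUTOFF_HZ) -> TriaxialSignal:
    """Second-order zero-lag low-pass of marker trajectories (default 6 Hz)."""
    return lowpass_triaxial(markers, cutoff, order=2)


def linear_velocity_norm(
    markers: TriaxialSignal, smooth_cutoff: float = SMOOTH_CUTOFF_HZ
) -> VelocityNorm:
    """Speed norm from (pre-filtered) marker positions.

    Central-difference differentiation per axis (one-sided at the edges),
    Euclidean norm, then the common 1.5 Hz fourth-order zero-lag smoothing.
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vel = np.gradient(markers.as_matrix(), 1.0 / markers.fs, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    smoothed = lowpass_zero_lag(TimeSeries(speed, fs=markers.fs), smooth_cutoff, order=4)
    return VelocityNorm.from_series(smoothed)


def sp_segments(vn: VelocityNorm, fraction: float = SP_FRACTION) -> SegmentList:
    """Threshold the amplitude-normalized speed norm at ``fraction``·vmax."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if vn.vmax <= 0:
        raise ValueError("vmax must be positive (all-zero velocity)")
    normalized = vn.series.values / vn.vmax
    return mask_to_segments(normalized > fraction, vn.series.fs)
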