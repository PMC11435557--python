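"""Signal containers, CSV I/O, filtering, bias compensation and synchronization.

Everything downstream operates on two containers: :class:`TriaxialSignal`
(raw gyroscope or marker channels) and :class:`TimeSeries` (a derived scalar
signal such as the angular-velocity norm Ω, rad/s, or the linear-velocity
norm |v|, mm/s). Both assume uniform sampling, nominally 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "TimeSeries",
    "TriaxialSignal",
    "read_imu_csv",
    "read_marker_csv",
    "read_velocity_csv",
    "vector_norm",
    "lowpass_zero_lag",
    "remove_static_bias",
    "resample_to",
    "sync_lag",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled scalar signal.

    Sample ``i`` occurs at ``start_time + i / fs`` seconds.
    """

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("TimeSeries values must be finite")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class TriaxialSignal:
    """Three synchronized channels (gyroscope rad/s, marker mm, or velocity mm/s)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    units: str = "rad/s"

    def __post_init__(self) -> None:
        chans = []
        for name in ("x", "y", "z"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.ndim != 1 or c.size < 1:
                raise ValueError(f"channel {name} must be a non-empty 1-D array")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"channel {name} contains non-finite values")
            chans.append(c)
        if not (chans[0].size == chans[1].size == chans[2].size):
            raise ValueError("channels must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "x", chans[0])
        object.__setattr__(self, "y", chans[1])
        object.__setattr__(self, "z", chans[2])

    def __len__(self) -> int:
        return self.x.size

    def as_matrix(self) -> np.ndarray:
        """(n, 3) channel matrix."""
        return np.column_stack([self.x, self.y, self.z])


def _fs_from_time(t: np.ndarray) -> float:
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-monotonic time column")
    fs = 1.0 / float(np.median(dt))
    # snap rates that are integral up to rounding of the time column
    return round(fs) if abs(fs - round(fs)) < 1e-3 * fs else fs


def _read_triaxial(path, cols, units, fs_override=None) -> TriaxialSignal:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", *cols) if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) < 2:
        raise ValueError("need at least 2 rows to infer sampling frequency")
    fs = fs_override if fs_override is not None else _fs_from_time(df["time_s"].to_numpy(float))
    if fs_override is not None:
        # still validate monotonicity
        _fs_from_time(df["time_s"].to_numpy(float))
    return TriaxialSignal(
        df[cols[0]].to_numpy(float),
        df[cols[1]].to_numpy(float),
        df[cols[2]].to_numpy(float),
        fs=fs,
        units=units,
    )


def read_imu_csv(path, fs_override: float | None = None) -> TriaxialSignal:
    """Read a gyroscope trial CSV (``time_s,gyro_x_rad_s,gyro_y_rad_s,gyro_z_rad_s``).

    Extra columns (e.g. accelerometer channels) are ignored. The sampling
    frequency is inferred from the median time step unless overridden.
    """
    return _read_triaxial(
        path, ("gyro_x_rad_s", "gyro_y_rad_s", "gyro_z_rad_s"), "rad/s", fs_override
    )


def read_marker_csv(path, fs_override: float | None = None) -> TriaxialSignal:
    """Read a marker-trajectory CSV (``time_s,x_mm,y_mm,z_mm``)."""
    return _read_triaxial(path, ("x_mm", "y_mm", "z_mm"), "mm", fs_override)


def read_velocity_csv(path, fs_override: float | None = None) -> TimeSeries:
    """Read a precomputed linear-velocity-norm CSV (``time_s,v_mm_s``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "v_mm_s") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) < 2:
        raise ValueError("need at least 2 rows to infer sampling frequency")
    fs = fs_override if fs_override is not None else _fs_from_time(df["time_s"].to_numpy(float))
    return TimeSeries(df["v_mm_s"].to_numpy(float), fs=fs)


def vector_norm(sig: TriaxialSignal) -> TimeSeries:
    """Per-sample Euclidean norm of the three channels (Ω for a gyroscope)."""
    return TimeSeries(np.linalg.norm(sig.as_matrix(), axis=1), fs=sig.fs)


def lowpass_zero_lag(ts: TimeSeries, cutoff: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass of the stated *effective* order.

    A filter of ``order // 2`` is designed and applied forward-backward
    (``filtfilt``), so magnitude response is squared and phase lag is zero.
    Reflective edge padding of three times the effective order limits
    end transients.
    """
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2 (forward-backward halves it)")
    nyq = ts.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    padlen = 3 * order
    if len(ts) <= padlen:
        raise ValueError(f"signal too short for zero-lag filtering (need > {padlen} samples)")
    b, a = butter(order // 2, cutoff / nyq)
    out = filtfilt(b, a, ts.values, padtype="even", padlen=padlen)
    return TimeSeries(out, fs=ts.fs, start_time=ts.start_time)


def lowpass_triaxial(sig: TriaxialSignal, cutoff: float, order: int = 4) -> TriaxialSignal:
    """Apply :func:`lowpass_zero_lag` channel-wise."""
    chans = [
        lowpass_zero_lag(TimeSeries(c, sig.fs), cutoff, order).values
        for c in (sig.x, sig.y, sig.z)
    ]
    return TriaxialSignal(*chans, fs=sig.fs, units=sig.units)


def remove_static_bias(
    sig: TriaxialSignal, static_window: tuple[int, int]
) -> TriaxialSignal:
    """Subtract per-channel means over a static window from the whole channel.

    Compensates constant gyroscope bias estimated from a static acquisition.
    The window is a half-open sample interval and must cover at least one
    second of signal.
    """
    start, stop = static_window
    if not (0 <= start < stop <= len(sig)):
        raise ValueError("static window out of signal bounds")
    if stop - start < sig.fs:
        raise ValueError("static window must span at least 1 s")
    chans = [c - c[start:stop].mean() for c in (sig.x, sig.y, sig.z)]
    return TriaxialSignal(*chans, fs=sig.fs, units=sig.units)


def resample_to(ts: TimeSeries, fs: float) -> TimeSeries:
    """Linear-interpolation resampling onto a target rate (same time span)."""
    if fs == ts.fs:
        return ts
    t_old = np.arange(len(ts)) / ts.fs
    t_new = np.arange(0.0, t_old[-1] + 0.5 / fs, 1.0 / fs)
    return TimeSeries(np.interp(t_new, t_old, ts.values), fs=fs, start_time=ts.start_time)


def sync_lag(a: TimeSeries, b: TimeSeries, max_lag: int) -> int:
    """Lag (samples) maximizing normalized cross-correlation within ±max_lag.

    A positive lag means ``b`` starts later than ``a``. Ties are broken by
    the smallest absolute lag. Used to align the optical reference stream
    with the IMU via the synchronization movement.
    """
    if a.fs != b.fs:
        raise ValueError("series must share a sampling frequency (resample first)")
    if max_lag >= min(len(a), len(b)):
        raise ValueError("max_lag must be smaller than both signal lengths")
    av = a.values - a.values.mean()
    bv = b.values - b.values.mean()
    sa, sb = float(np.sqrt(np.sum(av**2))), float(np.sqrt(np.sum(bv**2)))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("constant (zero-variance) input")
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag >= 0:
            n = min(len(av), len(bv) - lag)
            scores[k] = float(np.dot(av[:n], bv[lag : lag + n]))
        else:
            n = min(len(bv), len(av) + lag)
            scores[k] = float(np.dot(av[-lag : -lag + n], bv[:n]))
    scores /= sa * sb  # biased normalization: shared scale for all lags
    best = scores.max()
    candidates = lags[scores >= best - 1e-12]
    return int(candidates[np.argmin(np.abs(candidates))])
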