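"""Stride segmentation from the shank gyroscope or the lower-trunk accelerometer.

Strides are delimited by right-leg heel strikes.  The shank detector follows
the standard mid-swing-peak scheme: the medio-lateral shank angular velocity
shows a large positive peak at mid-swing followed by a sharp minimum at heel
strike.  The trunk detector is a heuristic surrogate: antero-posterior
acceleration peaks mark individual steps (two per stride) and right-side
events are selected by amplitude parity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import Trace3D, zero_phase_filter


@dataclass
class StrideParams:
    """Tunable thresholds for the event detectors (shank side)."""

    lowpass_hz: float = 5.0
    swing_min_rate: float = np.deg2rad(50.0)  # rad/s, absolute peak floor
    swing_rel_threshold: float = 0.5          # × median of qualifying peaks
    min_peak_separation_s: float = 0.5
    heel_strike_window_s: float = 0.4
    stride_bounds_s: tuple[float, float] = (0.4, 2.5)


@dataclass
class TrunkStrideParams:
    lowpass_hz: float = 5.0
    min_step_separation_s: float = 0.3
    rel_height: float = 0.3                   # × 95th percentile of the signal
    stride_bounds_s: tuple[float, float] = (0.4, 2.5)


@dataclass
class StrideSegmentation:
    """Ordered heel-strike sample indices and the stride durations they define."""

    heel_strike_indices: np.ndarray
    time: np.ndarray
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        self.heel_strike_indices = np.asarray(self.heel_strike_indices, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        if len(self.heel_strike_indices) and np.any(
            np.diff(self.heel_strike_indices) <= 0
        ):
            raise ValueError("heel-strike indices must be strictly increasing")

    @property
    def heel_strike_times(self) -> np.ndarray:
        return self.time[self.heel_strike_indices]

    @property
    def stride_durations(self) -> np.ndarray:
        return np.diff(self.heel_strike_times)

    @property
    def n_strides(self) -> int:
        return max(len(self.heel_strike_indices) - 1, 0)

    def __len__(self) -> int:
        return self.n_strides


def detect_strides_shank(gyro_ml: np.ndarray, fs: float, time: np.ndarray | None = None,
                         params: StrideParams | None = None) -> StrideSegmentation:
    """Heel strikes from the ML shank angular velocity (rad/s).

    Positive mid-swing peaks are located first; the heel strike is the first
    local minimum within ``heel_strike_window_s`` after each swing peak.
    """
    params = params or StrideParams()
    gyro_ml = np.asarray(gyro_ml, dtype=float)
    if len(gyro_ml) < 2 * fs:
        raise ValueError("need at least 2 s of data for stride detection")
    if time is None:
        time = np.arange(len(gyro_ml)) / fs

    x = zero_phase_filter(gyro_ml, fs, params.lowpass_hz, "lowpass")
    cand, _ = signal.find_peaks(x, height=params.swing_min_rate,
                                distance=int(params.min_peak_separation_s * fs))
    if len(cand) == 0:
        warnings.warn("no swing peaks found; returning empty segmentation")
        return StrideSegmentation(np.array([], dtype=int), time, "shank_gyro")
    height = params.swing_rel_threshold * np.median(x[cand])
    peaks = cand[x[cand] >= height]

    window = int(params.heel_strike_window_s * fs)
    events = []
    for p in peaks:
        seg = x[p: p + window + 1]
        minima, _ = signal.find_peaks(-seg)
        if len(minima):
            events.append(p + minima[0])
        else:
            events.append(p + int(np.argmin(seg)))
    idx = np.array(sorted(set(events)), dtype=int)
    idx = _enforce_stride_bounds(idx, time, params.stride_bounds_s)
    return StrideSegmentation(idx, time, "shank_gyro")


def detect_strides_trunk(acc: Trace3D, fs: float,
                         params: TrunkStrideParams | None = None) -> StrideSegmentation:
    """Right-side stride events from the lower-trunk AP acceleration.

    Step peaks (two per stride) are detected on the low-passed AP component;
    right steps are singled out by assuming alternating left/right peaks and
    keeping the parity with the larger mean amplitude (falling back to the
    parity with the steadier inter-event interval when amplitudes tie).
    The returned fiducial has a constant offset from the anatomical heel
    strike; stride durations are unaffected.
    """
    params = params or TrunkStrideParams()
    x = zero_phase_filter(acc.ap, fs, params.lowpass_hz, "lowpass")
    scale = np.percentile(np.abs(x), 95)
    if scale < 1e-6:
        warnings.warn("no activity in AP acceleration; returning empty segmentation")
        return StrideSegmentation(np.array([], dtype=int), acc.time, "trunk_accel")
    peaks, props = signal.find_peaks(x, height=params.rel_height * scale,
                                     distance=int(params.min_step_separation_s * fs))
    if len(peaks) < 4:
        warnings.warn("too few step peaks; returning empty segmentation")
        return StrideSegmentation(np.array([], dtype=int), acc.time, "trunk_accel")
    heights = props["peak_heights"]
    parities = [peaks[0::2], peaks[1::2]]
    mean_h = [heights[0::2].mean(), heights[1::2].mean()]
    if abs(mean_h[0] - mean_h[1]) > 0.02 * max(mean_h):
        idx = parities[int(np.argmax(mean_h))]
    else:
        cv = [np.std(np.diff(p)) / np.mean(np.diff(p)) if len(p) > 2 else np.inf
              for p in parities]
        idx = parities[int(np.argmin(cv))]
    idx = _enforce_stride_bounds(np.asarray(idx, dtype=int), acc.time,
                                 params.stride_bounds_s)
    return StrideSegmentation(idx, acc.time, "trunk_accel")


def _enforce_stride_bounds(idx: np.ndarray, time: np.ndarray,
                           bounds: tuple[float, float]) -> np.ndarray:
    """Drop events creating physiologically impossible stride durations."""
    lo, hi = bounds
    keep = [int(idx[0])] if len(idx) else []
    for k in idx[1:]:
        dt = time[k] - time[keep[-1]]
        if dt < lo:
            continue  # spurious double detection
        keep.append(int(k))
    keep = np.array(keep, dtype=int)
    if len(keep) > 1:
        durations = np.diff(time[keep])
        if np.any(durations > hi):
            warnings.warn("stride durations above the physiological bound detected")
    return keep


def stride_time_stats(seg: StrideSegmentation) -> tuple[float, float]:
    """Mean stride time (s) and stride-time variability (%).

    Variability is 100·SD/mean with the population SD (divide by n).
    """
    durations = seg.stride_durations
    if len(durations) < 2:
        raise ValueError("need at least 2 strides for stride-time statistics")
    mean = float(np.mean(durations))
    cv = 100.0 * float(np.std(durations)) / mean
    return mean, cv
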