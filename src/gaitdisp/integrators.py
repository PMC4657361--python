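"""Comparator displacement estimators based on numerical integration.

Two standard drift-mitigation schemes serve as baselines for the analytic
Fourier integration:

* windowed mean subtraction + trapezoidal rule (stride-based), and
* zero-phase high-pass filtering interleaved with trapezoidal integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import Trace3D, zero_phase_filter
from .segmentation import StrideSegmentation


@dataclass
class HighpassCutoffs:
    """Per-axis high-pass cut-offs (Hz) adapted to the gait band."""

    ml: float = 0.5
    vt: float = 1.0
    ap: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ml, self.vt, self.ap) <= 0:
            raise ValueError("cutoffs must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return self.ml, self.vt, self.ap


def _windowed_mean_subtract(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Per stride, subtract the mean over [stride i−1, stride i+1].

    ``bounds`` are the heel-strike sample offsets into x (first = 0, last =
    len(x)).  Edge strides use one-sided (truncated) windows.
    """
    out = np.empty_like(x)
    n_strides = len(bounds) - 1
    for i in range(n_strides):
        w_lo = bounds[max(i - 1, 0)]
        w_hi = bounds[min(i + 2, n_strides)]
        out[bounds[i]: bounds[i + 1]] = (
            x[bounds[i]: bounds[i + 1]] - np.mean(x[w_lo:w_hi], axis=0)
        )
    return out


def trapezoid_mean_subtracted(acc: Trace3D, seg: StrideSegmentation) -> Trace3D:
    """Stride-windowed mean subtraction + double trapezoidal integration.

    At each integration step the mean over a window of one stride to each
    side of the current stride is subtracted, which removes constant offsets
    and slow trends; the resulting displacement is per-stride mean-removed
    for comparability with the analytic estimator.
    """
    if seg.n_strides < 3:
        raise ValueError("need at least 3 strides for windowed mean subtraction")
    start, stop = seg.heel_strike_indices[0], seg.heel_strike_indices[-1]
    time = acc.time[start:stop]
    bounds = seg.heel_strike_indices - start
    data = acc.data[start:stop]

    a = _windowed_mean_subtract(data, bounds)
    vel = cumulative_trapezoid(a, time, axis=0, initial=0.0)
    vel = _windowed_mean_subtract(vel, bounds)
    disp = cumulative_trapezoid(vel, time, axis=0, initial=0.0)
    for i in range(seg.n_strides):
        sl = slice(bounds[i], bounds[i + 1])
        disp[sl] -= disp[sl].mean(axis=0)
    return Trace3D.from_data(time, disp, "displacement")


def highpass_double_integrate(acc: Trace3D, fs: float,
                              cutoffs: HighpassCutoffs | None = None,
                              passes: int = 3) -> Trace3D:
    """Zero-phase high-pass filtering + double trapezoidal integration.

    With ``passes=3`` the high-pass is applied before each integration and
    once more on the displacement (the guideline interleaving); ``passes=1``
    filters the acceleration only.
    """
    cutoffs = cutoffs or HighpassCutoffs()
    if passes not in (1, 3):
        raise ValueError("passes must be 1 or 3")
    out = np.empty((len(acc), 3))
    for col, cutoff in enumerate(cutoffs.as_tuple()):
        x = zero_phase_filter(acc.data[:, col], fs, cutoff, "highpass")
        x = cumulative_trapezoid(x, acc.time, initial=0.0)
        if passes == 3:
            x = zero_phase_filter(x, fs, cutoff, "highpass")
        x = cumulative_trapezoid(x, acc.time, initial=0.0)
        if passes == 3:
            x = zero_phase_filter(x, fs, cutoff, "highpass")
        out[:, col] = x
    return Trace3D.from_data(acc.time, out, "displacement")
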