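"""Method dispatch, stride-trace assembly and trial-level utilities.

The six estimator variants differ in how the strap-down quaternion is
obtained (motion-capture reference, EKF, or the rest-period attitude held
constant), which sensor segments the gait (shank gyroscope, lower-trunk
accelerometer, or none) and how the acceleration is integrated (analytic
Fourier, trapezoidal with windowed mean subtraction, or high-pass filtering
plus trapezoidal integration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline

from . import fourier, integrators, orientation, segmentation
from .core import ImuRecording, QuaternionSeries, Trace3D, strapdown_linear_acceleration, zero_phase_filter
from .integrators import HighpassCutoffs
from .segmentation import StrideParams, StrideSegmentation, TrunkStrideParams
from .synth import SyntheticTrial


@dataclass(frozen=True)
class MethodSpec:
    """One row of the tested-methods table."""

    rotation: str            # reference | ekf | initial
    segmentation_source: str  # shank_gyro | trunk_accel | none
    integration: str         # fourier | trapezoid | highpass


#: the six accepted estimator variants
METHODS = {
    "baseline": MethodSpec("reference", "shank_gyro", "fourier"),
    "A": MethodSpec("ekf", "shank_gyro", "fourier"),
    "B": MethodSpec("initial", "shank_gyro", "fourier"),
    "C": MethodSpec("ekf", "trunk_accel", "fourier"),
    "D": MethodSpec("ekf", "shank_gyro", "trapezoid"),
    "E": MethodSpec("ekf", "none", "highpass"),
}


@dataclass
class RunConfig:
    """Processing parameters shared by all methods."""

    n_harmonics: int = 20
    lowpass_hz: float = 12.0       # pre-integration zero-phase low-pass
    trim_s: float = 30.0           # discard at each end before statistics
    rest_s: float = 5.0            # standing-rest prefix used for bias/attitude
    spline_smoothing_hz: float = 0.35
    highpass_cutoffs: HighpassCutoffs = field(default_factory=HighpassCutoffs)
    stride_params: StrideParams = field(default_factory=StrideParams)
    trunk_stride_params: TrunkStrideParams = field(default_factory=TrunkStrideParams)
    ekf_params: orientation.OrientationFilterParams = field(
        default_factory=orientation.OrientationFilterParams
    )


@dataclass
class Trial:
    """Input streams for one walking trial."""

    trunk: ImuRecording
    shank: ImuRecording | None = None
    ref_quat: QuaternionSeries | None = None
    ref_displ: Trace3D | None = None

    @classmethod
    def from_synthetic(cls, st: SyntheticTrial) -> "Trial":
        return cls(trunk=st.trunk, shank=st.shank, ref_quat=st.truth_quat,
                   ref_displ=st.truth_displ)


def _validate_method(method: MethodSpec) -> None:
    if method not in METHODS.values():
        raise ValueError(f"unsupported method combination: {method}")


def _rest_slice(imu: ImuRecording, rest_s: float) -> slice:
    return slice(0, max(int(rest_s * imu.sampling_rate), 1))


def _orientation_for(trial: Trial, method: MethodSpec,
                     config: RunConfig) -> tuple[QuaternionSeries, ImuRecording]:
    """Quaternion series per the method's rotation source + bias-corrected IMU."""
    trunk = trial.trunk
    rest = _rest_slice(trunk, config.rest_s)
    bias = orientation.estimate_gyro_bias(trunk.gyro[rest])
    trunk_corr = replace(trunk, gyro=trunk.gyro - bias)
    if method.rotation == "reference":
        if trial.ref_quat is None:
            raise ValueError("method requires a reference quaternion stream")
        return trial.ref_quat, trunk_corr
    q0 = orientation.initial_attitude_from_rest(trunk.specific_force[rest])
    if method.rotation == "initial":
        return orientation.constant_orientation(trunk.time, q0), trunk_corr
    if method.rotation == "ekf":
        return orientation.ekf_orientation(trunk_corr, q0, config.ekf_params), trunk_corr
    raise ValueError(f"unknown rotation source {method.rotation!r}")


def _segmentation_for(trial: Trial, method: MethodSpec, lin_acc: Trace3D,
                      config: RunConfig) -> StrideSegmentation | None:
    if method.segmentation_source == "none":
        return None
    if method.segmentation_source == "shank_gyro":
        if trial.shank is None:
            raise ValueError("method requires a shank IMU stream for segmentation")
        shank = trial.shank
        rest = _rest_slice(shank, config.rest_s)
        bias = orientation.estimate_gyro_bias(shank.gyro[rest])
        return segmentation.detect_strides_shank(
            shank.gyro[:, 1] - bias[1], shank.sampling_rate, shank.time,
            config.stride_params,
        )
    if method.segmentation_source == "trunk_accel":
        return segmentation.detect_strides_trunk(
            lin_acc, trial.trunk.sampling_rate, config.trunk_stride_params
        )
    raise ValueError(f"unknown segmentation source {method.segmentation_source!r}")


def fourier_stride_displacement(
    lin_acc: Trace3D, seg: StrideSegmentation, n_harmonics: int = 20
) -> tuple[list[Trace3D], dict]:
    """Per-stride analytic double integration of the harmonic fit."""
    traces: list[Trace3D] = []
    recon_rmsd: list[float] = []
    reduced = 0
    for i in range(seg.n_strides):
        i0, i1 = seg.heel_strike_indices[i], seg.heel_strike_indices[i + 1]
        t_rel = lin_acc.time[i0:i1] - lin_acc.time[i0]
        T = lin_acc.time[i1] - lin_acc.time[i0]
        samples = lin_acc.data[i0:i1]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = fourier.fit_harmonics(samples, t_rel, T, n_harmonics)
        reduced += sum("reduced" in str(w.message) for w in caught)
        recon = model.evaluate(t_rel)
        for col in range(3):
            recon_rmsd.append(fourier.normalized_rmsd(samples[:, col], recon[:, col]))
        displ = fourier.analytic_integrate(model, order=2)
        traces.append(
            Trace3D.from_data(lin_acc.time[i0:i1], displ.evaluate(t_rel),
                              "displacement")
        )
    diagnostics = {
        "n_strides": seg.n_strides,
        "n_reduced_order": reduced,
        "recon_rmsd_pct": np.asarray(recon_rmsd),
    }
    return traces, diagnostics


def concatenate_with_spline(stride_traces: list[Trace3D],
                            seg: StrideSegmentation | None = None,
                            smoothing_hz: float = 0.35) -> Trace3D:
    """Join per-stride traces, smoothing boundary discontinuities.

    The jump at each stride boundary is estimated from local finite
    differences; the cumulative-jump staircase is smoothed with a cubic
    smoothing spline and the residual (staircase minus its smooth version) is
    subtracted.  Boundaries whose estimated jump is within the noise floor of
    the signal's second differences are left untouched, so an already
    continuous concatenation passes through unchanged.
    """
    if not stride_traces:
        raise ValueError("no stride traces to concatenate")
    time = np.concatenate([tr.time for tr in stride_traces])
    if np.any(np.diff(time) <= 0):
        raise ValueError("stride traces overlap or are out of order")
    data = np.concatenate([tr.data for tr in stride_traces], axis=0)
    n = len(time)
    boundaries = np.cumsum([len(tr) for tr in stride_traces[:-1]])
    dt = float(np.median(np.diff(time)))
    lam = dt / (2.0 * np.pi * smoothing_hz) ** 4

    out = data.copy()
    for col in range(3):
        y = data[:, col]
        dy = np.diff(y)
        d2 = np.abs(np.diff(dy))
        noise = max(float(np.median(d2)), 1e-15)
        stair = np.zeros(n)
        any_jump = False
        for b in boundaries:
            if b < 3 or b > n - 3:
                continue
            left = dy[b - 2] + (dy[b - 2] - dy[b - 3])
            right = dy[b] - (dy[b + 1] - dy[b])
            jump = dy[b - 1] - 0.5 * (left + right)
            if abs(jump) > 10.0 * noise:
                stair[b:] += jump
                any_jump = True
        if any_jump:
            smooth = make_smoothing_spline(time, stair, lam=lam)(time)
            out[:, col] = y - (stair - smooth)
    return Trace3D.from_data(time, out, stride_traces[0].quantity)


def piecewise_detrend(trace: Trace3D, seg: StrideSegmentation) -> Trace3D:
    """Remove the per-stride mean from each axis (piecewise-constant trend)."""
    data = trace.data.copy()
    idx = np.searchsorted(trace.time, seg.heel_strike_times)
    for i in range(len(idx) - 1):
        sl = slice(idx[i], idx[i + 1])
        if sl.stop > sl.start:
            data[sl] -= data[sl].mean(axis=0)
    return Trace3D.from_data(trace.time, data, trace.quantity)


def sync_streams(x: np.ndarray, y: np.ndarray, fs: float, max_lag: float) -> int:
    """Lag (samples) by which y is delayed relative to x.

    Maximizes the normalized cross-correlation within ±max_lag seconds.
    """
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    max_k = int(max_lag * fs)
    full = np.correlate(y, x, mode="full")  # index n-1 is zero lag
    center = len(x) - 1
    lo, hi = center - max_k, center + max_k + 1
    window = full[max(lo, 0): hi]
    return int(np.argmax(window) + max(lo, 0) - center)


def peak_to_trough(trace: Trace3D, seg: StrideSegmentation) -> dict:
    """Per-axis mean ± SD of the per-stride max − min, in mm."""
    idx = np.searchsorted(trace.time, seg.heel_strike_times)
    p2t = []
    for i in range(len(idx) - 1):
        sl = slice(idx[i], idx[i + 1])
        if sl.stop - sl.start < 2:
            continue
        seg_data = trace.data[sl]
        p2t.append(seg_data.max(axis=0) - seg_data.min(axis=0))
    p2t = np.asarray(p2t) * 1000.0
    if len(p2t) == 0:
        raise ValueError("no complete strides in trace")
    return {
        axis: (float(np.mean(p2t[:, col])), float(np.std(p2t[:, col])))
        for col, axis in enumerate(("ml", "vt", "ap"))
    }


def run_method(trial: Trial, method: MethodSpec | str,
               config: RunConfig | None = None) -> tuple[Trace3D, dict]:
    """Estimate the 3D trunk displacement with one of the tested methods."""
    if isinstance(method, str):
        method = METHODS[method]
    _validate_method(method)
    config = config or RunConfig()
    fs = trial.trunk.sampling_rate

    quats, trunk_corr = _orientation_for(trial, method, config)
    lin = strapdown_linear_acceleration(trunk_corr, quats)
    lin = Trace3D.from_data(
        lin.time, zero_phase_filter(lin.data, fs, config.lowpass_hz, "lowpass"),
        "acceleration",
    )
    seg = _segmentation_for(trial, method, lin, config)
    diagnostics: dict = {"method": method, "segmentation": seg}

    if method.integration == "fourier":
        assert seg is not None
        if seg.n_strides < 1:
            raise ValueError("no strides detected; cannot integrate")
        traces, diag = fourier_stride_displacement(lin, seg, config.n_harmonics)
        diagnostics.update(diag)
        displ = concatenate_with_spline(traces, seg, config.spline_smoothing_hz)
    elif method.integration == "trapezoid":
        assert seg is not None
        displ = integrators.trapezoid_mean_subtracted(lin, seg)
        diagnostics["n_strides"] = seg.n_strides
    elif method.integration == "highpass":
        displ = integrators.highpass_double_integrate(lin, fs,
                                                      config.highpass_cutoffs)
    else:
        raise ValueError(f"unknown integration {method.integration!r}")
    return displ, diagnostics


def method_vs_reference(trial: Trial, method: MethodSpec | str,
                        config: RunConfig | None = None
                        ) -> tuple[np.ndarray, np.ndarray, StrideSegmentation]:
    """Paired (est, ref) displacement samples in mm over steady-state strides.

    Runs the method, restricts both the estimate and the reference to strides
    fully inside the steady-state window (first/last ``trim_s`` seconds
    discarded), applies the same stride-based piecewise-constant trend
    removal to both, and returns pooled per-sample pairs in mm, along with
    the segmentation used.  A method without its own segmentation (high-pass
    integration) is detrended with the shank-based segmentation when a shank
    stream is present, otherwise with the global mean.
    """
    if isinstance(method, str):
        method = METHODS[method]
    config = config or RunConfig()
    if trial.ref_displ is None:
        raise ValueError("trial has no reference displacement")
    displ, diag = run_method(trial, method, config)
    seg = diag.get("segmentation")
    if seg is None or seg.n_strides == 0:
        if trial.shank is not None:
            seg = _segmentation_for(trial, METHODS["A"], displ, config)
        else:
            raise ValueError("no segmentation available for steady-state trimming")
    seg = steady_state_segmentation(seg, trial.trunk.time[0], trial.trunk.time[-1],
                                    config.trim_s)

    i0 = np.searchsorted(displ.time, seg.heel_strike_times[0])
    i1 = np.searchsorted(displ.time, seg.heel_strike_times[-1])
    est = displ.slice(slice(i0, i1))
    j0 = np.searchsorted(trial.ref_displ.time, est.time[0])
    ref = trial.ref_displ.slice(slice(j0, j0 + len(est)))
    if len(ref) != len(est) or np.any(np.abs(ref.time - est.time) > 1e-6):
        raise ValueError("reference and estimate are not on a common grid")

    est = piecewise_detrend(est, seg)
    ref = piecewise_detrend(ref, seg)
    return est.data * 1000.0, ref.data * 1000.0, seg


def steady_state_segmentation(seg: StrideSegmentation, t_start: float,
                              t_end: float, trim_s: float) -> StrideSegmentation:
    """Keep only strides fully inside [t_start + trim, t_end − trim]."""
    times = seg.heel_strike_times
    lo, hi = t_start + trim_s, t_end - trim_s
    keep = []
    for i in range(len(times) - 1):
        if times[i] >= lo and times[i + 1] <= hi:
            keep.extend([i, i + 1])
    if not keep:
        raise ValueError("no strides remain after trimming")
    uniq = sorted(set(keep))
    return StrideSegmentation(seg.heel_strike_indices[uniq], seg.time, seg.source)
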