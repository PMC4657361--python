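"""Per-stride truncated Fourier modelling and closed-form analytic integration.

This is the core of the displacement estimator.  Each stride of linear
acceleration is modelled per axis as

    acc(t) = a(0) + Σ_{k=1..N} [ a(k) cos(2πk t/T) + b(k) sin(2πk t/T) ]

with t measured from the detected heel strike and T the stride duration.
Because the antiderivatives of the basis functions are known in closed form,
velocity and displacement follow analytically and without integration drift:
dropping the constant term a(0) (detrending a constant), the mean-subtracted
velocity has coefficients (T/2π)(1/k)·(a sin − b cos) and the displacement
−(T/2π)²(1/k²)·(a cos + b sin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AXES

_QUANTITY_BY_ORDER = {0: "acceleration", 1: "velocity", 2: "displacement"}


@dataclass
class HarmonicStrideModel:
    """Truncated Fourier series of one stride, all three axes.

    a0 : (3,) constant terms; a, b : (N, 3) cosine/sine coefficients, axis
    columns in ML, VT, AP order.
    """

    T: float
    N: int
    a0: np.ndarray
    a: np.ndarray
    b: np.ndarray
    quantity: str = "acceleration"
    integration_order: int = 0

    def __post_init__(self) -> None:
        self.a0 = np.atleast_1d(np.asarray(self.a0, dtype=float))
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.T <= 0:
            raise ValueError("stride duration T must be positive")
        if self.N < 1:
            raise ValueError("harmonic order N must be >= 1")
        if self.a.shape != (self.N, self.a0.shape[0]) or self.a.shape != self.b.shape:
            raise ValueError("coefficient arrays must have shape (N, n_axes)")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the series at times t (seconds from stride onset)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        k = np.arange(1, self.N + 1)
        phase = 2.0 * np.pi * np.outer(t, k) / self.T
        return self.a0 + np.cos(phase) @ self.a + np.sin(phase) @ self.b


def design_matrix(times: np.ndarray, T: float, N: int) -> np.ndarray:
    """OLS basis {1, cos(2πkt/T), sin(2πkt/T)} evaluated at the sample times."""
    times = np.asarray(times, dtype=float)
    k = np.arange(1, N + 1)
    phase = 2.0 * np.pi * np.outer(times, k) / T
    return np.hstack([np.ones((len(times), 1)), np.cos(phase), np.sin(phase)])


def fit_harmonics(samples: np.ndarray, times: np.ndarray, T: float,
                  N: int = 20) -> HarmonicStrideModel:
    """Least-squares Fourier coefficients of one stride.

    ``samples`` is (M,) or (M, n_axes) with times in [0, T) relative to the
    stride onset.  When M < 2N + 1 the order is reduced to ⌊(M−1)/2⌋ with a
    warning so the problem stays over-determined.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    times = np.asarray(times, dtype=float)
    m = samples.shape[0]
    if m < 3:
        raise ValueError("need at least 3 samples per stride")
    if len(times) != m:
        raise ValueError("times and samples must have equal length")
    if m < 2 * N + 1:
        n_eff = (m - 1) // 2
        warnings.warn(
            f"stride has {m} samples; harmonic order reduced from {N} to {n_eff}"
        )
        N = n_eff
    basis = design_matrix(times, T, N)
    coef, *_ = np.linalg.lstsq(basis, samples, rcond=None)
    return HarmonicStrideModel(
        T=T, N=N, a0=coef[0], a=coef[1: N + 1], b=coef[N + 1:],
        quantity="acceleration", integration_order=0,
    )


def analytic_integrate(model: HarmonicStrideModel, order: int) -> HarmonicStrideModel:
    """Closed-form single (order=1) or double (order=2) time integration.

    The constant terms a(0) are set to zero first (for cyclical movement the
    linear acceleration has zero mean), so the outputs are the mean-subtracted
    per-stride velocity and displacement.
    """
    if model.quantity != "acceleration" or model.integration_order != 0:
        raise ValueError("analytic integration starts from an acceleration model")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    k = np.arange(1, model.N + 1, dtype=float)[:, None]
    scale = model.T / (2.0 * np.pi)
    if order == 1:
        a_out = -scale / k * model.b
        b_out = scale / k * model.a
    else:
        a_out = -(scale**2) / k**2 * model.a
        b_out = -(scale**2) / k**2 * model.b
    return HarmonicStrideModel(
        T=model.T, N=model.N, a0=np.zeros_like(model.a0), a=a_out, b=b_out,
        quantity=_QUANTITY_BY_ORDER[order], integration_order=order,
    )


def normalized_rmsd(x: np.ndarray, xhat: np.ndarray) -> float:
    """100 · RMS(x − xhat) / RMS(x), the reconstruction-adequacy check."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("sequences must have equal shape")
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("reference signal has zero RMS")
    return 100.0 * float(np.sqrt(np.mean((x - xhat) ** 2)) / rms)


@dataclass
class GibbsResult:
    overshoot_fraction: float
    oscillation_frequency_hz: float


def gibbs_overshoot_fraction(jump_signal: np.ndarray, N: int,
                             period_s: float = 1.0,
                             oversample: int = 64) -> GibbsResult:
    """Overshoot of the order-N Fourier partial sum near a step discontinuity.

    ``jump_signal`` is one period, uniformly sampled.  The largest jump is
    located from the first differences; the partial sum is evaluated on a
    dense grid around it and the maximum excursion beyond the adjacent
    plateau, divided by the jump height, is returned together with the Gibbs
    oscillation frequency ≈ N/T.  For large N the fraction approaches
    (1/π)·Si(π) − 1/2 ≈ 0.0895 — about 9% of the jump, independent of N.
    """
    x = np.asarray(jump_signal, dtype=float)
    m = len(x)
    if m < 8:
        raise ValueError("signal too short")
    diffs = np.abs(np.diff(x))
    j = int(np.argmax(diffs))
    med = np.median(diffs)
    if diffs[j] < 5.0 * max(med, 1e-15) or diffs[j] == 0.0:
        raise ValueError("signal has no dominant step discontinuity")

    quarter = max(m // 8, 2)
    lo_level = np.median(x[max(j - quarter, 0): j + 1])
    hi_level = np.median(x[j + 1: j + 1 + quarter])
    jump = hi_level - lo_level
    if jump == 0:
        raise ValueError("zero jump height")

    times = np.arange(m) / m * period_s
    model = fit_harmonics(x, times, period_s, N)
    t_jump = times[j + 1] if j + 1 < m else times[-1]
    # a few Gibbs lobes on each side of the jump
    half = 3.0 * period_s / N
    t_dense = np.linspace(t_jump - half, t_jump + half, oversample * N // 4 + 101)
    recon = model.evaluate(np.mod(t_dense, period_s))[:, 0]
    over = np.max(recon) - max(lo_level, hi_level)
    under = min(lo_level, hi_level) - np.min(recon)
    fraction = float(max(over, under) / abs(jump))
    return GibbsResult(fraction, N / period_s)
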