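"""Bland–Altman method-comparison statistics.

Constant limits of agreement are the mean difference ± 1.96 SD of the
differences.  When the differences or their spread vary with the measurand,
regression-based limits are used instead: a least-squares line for the
difference D versus the pair mean A, plus 2.46 × a least-squares line for the
absolute residuals (2.46 = √(π/2) · 1.96, the half-normal correction for
working with absolute residuals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: multiplier converting the absolute-residual regression line into limits
RESIDUAL_MULTIPLIER = 2.46
LA_MULTIPLIER = 1.96


@dataclass
class BlandAltman:
    """Constant limits of agreement for one axis (units follow the input)."""

    md: float
    sd_diff: float
    la_lower: float
    la_upper: float

    @property
    def la_width(self) -> float:
        return self.la_upper - self.la_lower

    @property
    def la_half_width(self) -> float:
        return LA_MULTIPLIER * self.sd_diff


@dataclass
class RegressionLimits:
    """Regression-based limits: D̂(A) ± 2.46 · R̂(A)."""

    d_slope: float
    d_intercept: float
    r_slope: float
    r_intercept: float

    def difference_at(self, a: np.ndarray) -> np.ndarray:
        return self.d_slope * np.asarray(a, dtype=float) + self.d_intercept

    def residual_scale_at(self, a: np.ndarray) -> np.ndarray:
        return self.r_slope * np.asarray(a, dtype=float) + self.r_intercept

    def limits_at(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = self.difference_at(a)
        r = RESIDUAL_MULTIPLIER * self.residual_scale_at(a)
        return d - r, d + r

    def width_at(self, a: np.ndarray) -> np.ndarray:
        return 2.0 * RESIDUAL_MULTIPLIER * self.residual_scale_at(a)


def bland_altman(est: np.ndarray, ref: np.ndarray) -> BlandAltman:
    """Mean difference and constant limits of agreement (population SD)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1-D arrays")
    if len(est) < 2:
        raise ValueError("need at least 2 paired samples")
    d = est - ref
    md = float(np.mean(d))
    sd = float(np.std(d))
    return BlandAltman(md, sd, md - LA_MULTIPLIER * sd, md + LA_MULTIPLIER * sd)


def regression_limits(est: np.ndarray, ref: np.ndarray) -> RegressionLimits:
    """Fit the non-uniform-differences regression limits."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or len(est) < 10:
        raise ValueError("need at least 10 paired samples")
    a = 0.5 * (est + ref)
    d = est - ref
    if np.std(a) < 1e-12:
        raise ValueError("pair means are degenerate (zero variance)")
    d_slope, d_intercept = np.polyfit(a, d, 1)
    resid = d - (d_slope * a + d_intercept)
    r_slope, r_intercept = np.polyfit(a, np.abs(resid), 1)
    return RegressionLimits(float(d_slope), float(d_intercept),
                            float(r_slope), float(r_intercept))


def representative_la_width(reg: RegressionLimits, a_values: np.ndarray) -> float:
    """Average regression-based LA width over the central 95% of the measurand."""
    a = np.asarray(a_values, dtype=float)
    lo, hi = np.percentile(a, [2.5, 97.5])
    sel = a[(a >= lo) & (a <= hi)]
    return float(np.mean(reg.width_at(sel)))


@dataclass
class AgreementReport:
    """Per-axis agreement statistics (mm) between an estimate and a reference."""

    per_axis: dict[str, BlandAltman]
    regression: dict[str, RegressionLimits] | None = None
    representative_width_mm: dict[str, float] | None = None

    def summary(self) -> str:
        lines = ["axis      MD (mm)   LA half-width (mm)   LA width (mm)"]
        for axis, ba in self.per_axis.items():
            lines.append(
                f"{axis:<8} {ba.md:9.4f} {ba.la_half_width:18.3f}"
                f" {ba.la_width:15.3f}"
            )
        if self.regression:
            lines.append("")
            lines.append("regression limits: D = slope·A + intercept"
                         " ± 2.46 (r_slope·A + r_intercept)")
            for axis, reg in self.regression.items():
                lines.append(
                    f"{axis:<8} D = {reg.d_slope:.4f} A + {reg.d_intercept:.4f} "
                    f"± 2.46 ({reg.r_slope:.4f} A + {reg.r_intercept:.4f})"
                )
        return "\n".join(lines)


def agreement_report(est_mm: np.ndarray, ref_mm: np.ndarray,
                     with_regression: bool = False) -> AgreementReport:
    """Build a per-axis report from (n, 3) paired displacement samples in mm."""
    est_mm = np.asarray(est_mm, dtype=float)
    ref_mm = np.asarray(ref_mm, dtype=float)
    axes = ("ml", "vt", "ap")
    per_axis = {ax: bland_altman(est_mm[:, i], ref_mm[:, i])
                for i, ax in enumerate(axes)}
    regression = None
    rep = None
    if with_regression:
        regression, rep = {}, {}
        for i, ax in enumerate(axes):
            reg = regression_limits(est_mm[:, i], ref_mm[:, i])
            regression[ax] = reg
            rep[ax] = representative_la_width(reg, 0.5 * (est_mm[:, i] + ref_mm[:, i]))
    return AgreementReport(per_axis, regression, rep)
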