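"""Bland-Altman agreement with regression-based limits.

When the spread of the differences varies with the measured value, constant
limits of agreement (MD ± 1.96 SD) overestimate the band.  The regression
approach fits the difference D and the absolute residuals against the pair
mean A, giving limits D̂(A) ± 2.46·R̂(A) that track the heteroscedasticity.
"""

import numpy as np

from gaitdisp import (TrialConfig, agreement_report, generate_trial,
                      method_vs_reference, representative_la_width)
from gaitdisp.pipeline import Trial

trial = generate_trial(TrialConfig(speed_kmh=6, seed=9))
est, ref, _ = method_vs_reference(Trial.from_synthetic(trial), "A")

report = agreement_report(est, ref, with_regression=True)
print(report.summary())
print()
for axis in ("ml", "vt", "ap"):
    const = report.per_axis[axis].la_width
    rep = report.representative_width_mm[axis]
    print(f"{axis.upper()}: constant LA width {const:.2f} mm, "
          f"regression-based representative width {rep:.2f} mm")

# The representative width averages 2·2.46·R̂(A) over the central 95% of
# the measured displacements; on heteroscedastic differences it avoids the
# overestimation of the constant band.
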