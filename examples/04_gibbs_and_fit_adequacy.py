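"""Gibbs overshoot of truncated Fourier sums and fit adequacy.

Because detected strides are not exactly cyclical (f(0) != f(T)), the
per-stride Fourier model sees a step discontinuity at the stride boundary.
Truncated partial sums overshoot such a step by ~9% of the jump regardless
of the order N; after double integration the k-th ripple is attenuated by
1/k², so the displacement error stays sub-millimetre.
"""

import numpy as np

from gaitdisp import TrialConfig, generate_trial, gibbs_overshoot_fraction, run_method
from gaitdisp.pipeline import Trial

step = np.zeros(4096)
step[2048:] = 1.0
for order in (20, 200):
    res = gibbs_overshoot_fraction(step, order)
    print(f"N={order:>3}: overshoot {100 * res.overshoot_fraction:.2f} % of the "
          f"jump, ripple frequency {res.oscillation_frequency_hz:.0f}/T Hz")

trial = generate_trial(TrialConfig(speed_kmh=5, seed=2))
_, diag = run_method(Trial.from_synthetic(trial), "A")
rmsd = diag["recon_rmsd_pct"]
print(f"per-stride normalized reconstruction RMSD: median "
      f"{np.median(rmsd):.2f} %, 95th percentile {np.percentile(rmsd, 95):.2f} %")

# The overshoot stays ~9% at any order (the Gibbs phenomenon), while the
# order-20 fit reconstructs gait acceleration well below the 5% adequacy
# criterion.
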