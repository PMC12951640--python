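"""Why test-time instance normalization helps under domain shift.

Applies a per-channel affine intensity perturbation (emulating a scanner /
protocol change) to a feature map and compares the output of (a) batch-norm
inference with stored training statistics and (b) test-time instance
normalization.  TTIN's output is unchanged by construction — the instance
statistics absorb the shift — while BN statistics produce a mismatched
normalization.
"""

import numpy as np

from lesionseg.normalization import NormalizationState, normalize_eval_bn, normalize_ttin

rng = np.random.default_rng(7)
st = NormalizationState.create("BN", 4)
st.gamma = rng.normal(1.0, 0.2, size=4)
st.beta = rng.normal(0.0, 0.3, size=4)
st.moving_mean = np.zeros(4)  # training-domain statistics
st.moving_var = np.ones(4)

x = rng.normal(0.0, 1.0, size=(1, 4, 16, 16))  # in-domain feature map
shifted = 1.8 * x + 0.9  # domain-shifted feature map (per-channel affine)

for name, fn in (("BN train stats", lambda v: normalize_eval_bn(v, st)),
                 ("TTIN", lambda v: normalize_ttin(v, st))):
    drift = np.abs(fn(shifted) - fn(x)).max()
    print(f"{name:>15}: max output change under the shift = {drift:.2e}")
print("TTIN output is invariant (up to the epsilon guard); BN is not.")
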