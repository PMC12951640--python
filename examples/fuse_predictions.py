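"""Two-threshold lesion fusion versus plain majority voting.

Builds 24 binary masks emulating the multi-orientation predictions of one
subject: every pass agrees on a lesion's high-confidence core, only 10 of
24 recover its full extent, and 14 of 24 share a spurious blob.  The
two-threshold fusion grows the detected core (confidence > tau1 = 16) into
all connected candidate voxels (confidence > tau2 = 7), recovering the full
lesion while rejecting the spurious blob, which never reaches detection
confidence.  Majority voting (13 of 24) keeps the blob and truncates the
lesion.
"""

import numpy as np

from lesionseg.fusion import FusionParams, confidence_map, fuse, majority_vote
from lesionseg.metrics import lesion_metrics, voxel_metrics

shape = (24, 24, 24)
core = np.zeros(shape, dtype=np.uint8)
core[6:10, 6:10, 6:10] = 1  # unambiguous lesion centre
shell = np.zeros(shape, dtype=np.uint8)
shell[4:12, 4:12, 4:12] = 1
shell &= ~core  # full lesion extent around the core
blob = np.zeros(shape, dtype=np.uint8)
blob[16:19, 16:19, 16:19] = 1  # spurious detection
truth = core | shell

masks = []
for i in range(24):
    m = core.copy()
    if i < 10:
        m |= shell  # only 10 passes see the full extent
    if i < 14:
        m |= blob  # 14 passes share the false positive
    masks.append(m)

cmap = confidence_map(masks)
print(f"confidence: core={cmap.C[7, 7, 7]}, shell={cmap.C[4, 4, 4]}, blob={cmap.C[17, 17, 17]} (of 24)")

fused = fuse(masks, FusionParams(tau1=16, tau2=7))
voted = majority_vote(masks)  # strict majority: > 12 of 24
for name, mask in (("two-threshold fusion", fused), ("majority vote", voted)):
    dsc = voxel_metrics(mask, truth)[0]
    ltpr, lfpr = lesion_metrics(mask, truth)
    print(f"{name:>20}: Dice {dsc:.3f}  LTPR {ltpr:.2f}  LFPR {lfpr:.2f}")
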