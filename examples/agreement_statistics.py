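"""Validating an automated reader against a reference: ICC, Bland-Altman, Dice.

Simulates paired NWU measurements (automated vs manual, with a small bias
and reader noise) and two overlapping segmentations, then computes the
agreement statistics used to validate automated pipelines.
"""

import numpy as np

from nwu_kit import VoxelMask, bland_altman, dice, icc_2_1

rng = np.random.default_rng(7)
manual = rng.uniform(5, 35, 40)                      # reference NWU, %
automated = manual + 0.6 + rng.normal(0.0, 1.5, 40)  # small bias + noise

icc = icc_2_1(automated, manual)
ba = bland_altman(automated, manual)
print(f"ICC(2,1)            : {icc.icc:.3f} "
      f"(95% CI {icc.icc_ci[0]:.3f}-{icc.icc_ci[1]:.3f}, n={icc.n})")
print(f"Bland-Altman bias   : {ba.bias:+.2f} points")
print(f"limits of agreement : [{ba.loa_low:+.2f}, {ba.loa_high:+.2f}]")

a = np.zeros((20, 20, 10), dtype=np.uint8)
a[4:14, 4:14, 2:8] = 1
b = np.roll(a, 2, axis=0)  # the "automated" mask, shifted by 2 voxels
d = dice(VoxelMask(a, (1.0, 1.0, 1.0)), VoxelMask(b, (1.0, 1.0, 1.0)))
print(f"Dice of shifted mask: {d:.3f}")

# An ICC near 1 with narrow limits of agreement means the automated reader
# can replace the manual one; the Dice value quantifies spatial overlap of
# the segmentations themselves.
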