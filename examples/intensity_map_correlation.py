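"""Masked FFT cross-correlation and pixel statistics of two intensity maps.

Generates channel pairs sharing a controlled fraction of cluster centres,
then quantifies their spatial relationship with the mask-normalised
cross-correlation c(r) and the pixel-wise Pearson coefficient.
c(r) = 1 at all r means no spatial relationship.
"""

import numpy as np

from tfmap import field_maps as fm
from tfmap import synth

for coloc in (0.0, 0.5, 1.0):
    m1, m2, mask, _ = synth.gen_intensity_pair(coloc, seed=7)
    r_nm, c = fm.cross_correlation(m1, m2, mask)
    short = np.nanmean(c[(r_nm > 160) & (r_nm <= 500)])
    rho, quadrants = fm.pixel_correlation(m1.data, m2.data, mask)
    print(f"colocalization {coloc:.1f}: c(r<500nm) = {short:.2f}, "
          f"pixel rho = {rho:+.2f}, both-high pixel fraction = "
          f"{quadrants['high_high']:.2f}")

m1, _, mask, _ = synth.gen_intensity_pair(1.0, seed=8)
r_nm, c_auto = fm.cross_correlation(m1, m1, mask)
tail = np.nanmean(c_auto[(r_nm >= 1500) & (r_nm <= 3000)])
perm = fm.permute_within_mask(m1, mask, seed=9)
_, c_null = fm.cross_correlation(m1, perm, mask)
null = np.nanmean(c_null[(r_nm > 160) & (r_nm <= 3000)])
print(f"self-correlation: c just above the pixel scale = {c_auto[2]:.2f}, "
      f"large-r mean = {tail:.2f}")
print(f"permutation null: mean c = {null:.2f}")
print("  -> clustered maps start well above 1 and converge to 1; permuting"
      " pixels inside the mask destroys all structure (c = 1 throughout).")
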