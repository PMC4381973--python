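"""Region-resolved diffusion analysis: mask splitting and mixture fitting.

Tracks are cut at mask boundaries without re-linking, per-fragment diffusion
coefficients come from linear MSD fits, and the population structure is read
off a Gaussian mixture on log10 D.
"""

import numpy as np

from tfmap import diffusion as dif
from tfmap import synth

spec = synth.TrackMixtureSpec(
    populations=[(1.4, 0.36), (0.017, 0.64)],  # fast vs bound, as inside a cluster
    dt_s=0.01, n_tracks=300, track_length=20, loc_noise_sd_nm=20.0,
)
tracks = synth.gen_mixture_tracks(spec, seed=10, ndim=2)

fits = dif.estimate_D_per_track(tracks, min_frames=8, r2_min=0.8)
accepted = fits[fits["accepted"]]
print(f"{len(accepted)} of {len(fits)} MSD fits accepted (R^2 >= 0.8)")

mix = dif.d_histogram_mixture(fits.loc[fits.D_um2_s > 0, "D_um2_s"], k=2)
for d, sd_log, w in mix.components:
    kind = "fast " if d > 0.2 else "bound"
    print(f"  {kind} population: D = {d:.3f} um^2/s, weight = {w:.2f}")
print("  -> weights recover the generator's 36/64 fast/bound split; the"
      " bound D reflects the 20 nm localization-noise floor, not motion.")

# identity limit: a full-field mask leaves the fragment set unchanged
full = np.ones((400, 400), bool)
inside, outside = dif.split_tracks_by_mask(tracks, full, pixel_nm=100.0,
                                           origin_nm=(-20000, -20000))
print(f"full-field mask: {len(outside.data)} detections outside "
      f"({len(inside.data)} inside = all)")
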