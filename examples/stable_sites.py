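"""Stable binding sites from a bound/diffusing track mixture.

Under slow acquisition a bound molecule appears as a near-stationary track;
a track qualifies as a stable site when every step and its end-to-end
displacement stay under 50 nm for at least the duration cutoff.
"""

from tfmap import synth, tracking

spec = synth.TrackMixtureSpec(
    populations=[(0.0, 0.64), (1.4, 0.36)],  # bound vs freely diffusing
    dt_s=0.5, n_tracks=200, track_length=12, loc_noise_sd_nm=10.0,
)
tracks = synth.gen_mixture_tracks(spec, seed=6, ndim=2)

sites = tracking.stable_sites(tracks, max_disp_nm=50.0, min_duration_s=2.0,
                              single_frame="bound")
hist, mean_res, sem = tracking.residence_stats(sites)

print(f"{len(sites)} stable sites from {tracks.n_tracks} tracks "
      f"({len(sites) / tracks.n_tracks:.0%}; generator bound fraction 64%)")
print(f"mean residence time {mean_res:.1f} +/- {sem:.1f} s")
print("  -> the passing fraction tracks the bound population; fast-diffusing"
      " molecules fail the 50 nm displacement bound.")

counts = tracking.detections_per_frame(tracks.data)
print(f"detections per frame: min {counts.min()}, max {counts.max()}"
      " (constant illumination -> flat profile)")
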