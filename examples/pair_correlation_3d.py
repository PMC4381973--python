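"""3D pair correlation of binding-site catalogs and the fluctuation-model fit.

Generates a uniform and a Gaussian-clustered catalog of 7000 sites in a 5 µm
nucleus, estimates g(r) with a 10x random catalog, and fits the clustering
amplitude A and range epsilon to the clustered curve.
"""

import numpy as np

from tfmap import cluster_stats as cs
from tfmap import synth

sphere = synth.NuclearVolume(shape="sphere", radius_um=5.0)

uniform = synth.gen_uniform_points(7000, sphere, seed=1)
g_uniform = cs.pair_correlation_3d(uniform, dr_nm=50.0, random_factor=10,
                                   volume=sphere, seed=2)
sel = (g_uniform.r_nm >= 200) & (g_uniform.r_nm <= 1000)
print(f"uniform catalog: mean g(200-1000 nm) = {np.nanmean(g_uniform.g[sel]):.3f}")
print("  -> 1 means complete spatial randomness: no clustering.")

spec = synth.ClusterSpec(n_points=7000, n_clusters=70, sigma_nm=200.0,
                         min_separation_nm=80.0)
clustered = synth.gen_clustered_points(spec, sphere, seed=3)
g_clustered = cs.pair_correlation_3d(clustered, dr_nm=50.0, random_factor=10,
                                     volume=sphere, seed=4)
first = np.nonzero(g_clustered.dd > 0)[0][0]
print(f"clustered catalog: g at first informative bin "
      f"(r = {g_clustered.r_nm[first]:.0f} nm) = {g_clustered.g[first]:.1f}")
print("  -> values far above 1 at short range signal clustering; the decay"
      " scale tracks the cluster size.")

fit = cs.fit_fluctuation_model(g_clustered, s_bar_nm=20.0, a_bar_nm=100.0)
print(f"fluctuation-model fit: amplitude A = {fit.amplitude:.1f}, "
      f"range epsilon = {fit.range_nm:.0f} nm")
print("  -> A is the in-cluster density enrichment over the nuclear mean;"
      " epsilon is proportional to the cluster radius (sigma = 200 nm here).")
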