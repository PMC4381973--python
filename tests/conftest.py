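import numpy as np
import pytest

from tfmap import synth


@pytest.fixture(scope="session")
def sphere_5um():
    return synth.NuclearVolume(shape="sphere", radius_um=5.0)


@pytest.fixture(scope="session")
def sphere_2um():
    return synth.NuclearVolume(shape="sphere", radius_um=2.0)


@pytest.fixture(scope="session")
def clustered_catalog(sphere_5um):
    """Moderate clustered catalog shared by the clustering statistics tests."""
    spec = synth.ClusterSpec(n_points=2000, n_clusters=20, sigma_nm=200.0,
                             min_separation_nm=0.0)
    return synth.gen_clustered_points(spec, sphere_5um, seed=11)


def brute_force_pair_hist(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """O(n^2) non-redundant pair-distance histogram with (lo, hi] bins."""
    from scipy.spatial.distance import pdist

    d = np.sort(pdist(points))
    cum = np.searchsorted(d, edges, side="right")
    return np.diff(cum).astype(float)
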