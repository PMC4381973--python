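"""Synthetic-data generators with retained ground truth.

Every generator is deterministic given a seed and returns, next to the data,
the ground truth needed to score downstream analyses (cluster labels, track
population labels, true site positions).  Coordinates are in nanometres,
diffusion coefficients in µm²/s, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import Delaunay

NM_PER_UM = 1000.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NuclearVolume:
    """A bounded nuclear volume: a sphere or the convex hull of a point set.

    Parameters
    ----------
    shape : {"sphere", "hull"}
    radius_um : sphere radius in micrometres (ignored for hulls).
    center_nm : sphere centre, nm.
    hull_points_nm : (n, 3) array spanning the hull (required for ``"hull"``).
    """

    shape: str = "sphere"
    radius_um: float = 5.0
    center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hull_points_nm: np.ndarray | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "hull"):
            raise ValueError(f"unknown volume shape {self.shape!r}")
        if self.shape == "sphere" and self.radius_um <= 0:
            raise ValueError("sphere radius must be positive")
        if self.shape == "hull":
            pts = np.asarray(self.hull_points_nm, dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
                raise ValueError("hull volume needs >= 4 points in 3D")
            object.__setattr__(self, "hull_points_nm", pts)

    @property
    def radius_nm(self) -> float:
        return self.radius_um * NM_PER_UM

    def _delaunay(self) -> Delaunay:
        # cached lazily on the (frozen) instance
        tri = getattr(self, "_tri", None)
        if tri is None:
            tri = Delaunay(self.hull_points_nm)
            object.__setattr__(self, "_tri", tri)
        return tri

    def contains(self, points_nm: np.ndarray) -> np.ndarray:
        points_nm = np.atleast_2d(points_nm)
        if self.shape == "sphere":
            d = np.linalg.norm(points_nm - np.asarray(self.center_nm), axis=1)
            return d <= self.radius_nm
        return self._delaunay().find_simplex(points_nm) >= 0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points i.i.d. uniform inside the volume (nm)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.shape == "sphere":
            direction = rng.standard_normal((n, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            r = self.radius_nm * rng.random(n) ** (1.0 / 3.0)
            return np.asarray(self.center_nm) + direction * r[:, None]
        # rejection sampling in the hull's bounding box
        pts = self.hull_points_nm
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        out = np.empty((0, 3))
        while out.shape[0] < n:
            cand = rng.uniform(lo, hi, size=(max(2 * n, 64), 3))
            cand = cand[self.contains(cand)]
            out = np.vstack([out, cand])
        return out[:n]


# ---------------------------------------------------------------------------
# point catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian-cluster catalog: ``n_points`` split across ``n_clusters``
    isotropic Gaussian clouds of S.D. ``sigma_nm`` with a hard-core minimum
    pairwise separation ``min_separation_nm`` between all points."""

    n_points: int
    n_clusters: int
    sigma_nm: float
    min_separation_nm: float = 0.0

    def __post_init__(self):
        if not (self.n_points >= self.n_clusters >= 1):
            raise ValueError("need n_points >= n_clusters >= 1")
        if self.sigma_nm <= 0:
            raise ValueError("sigma must be positive")
        if self.min_separation_nm < 0:
            raise ValueError("min_separation must be >= 0")


def gen_uniform_points(n: int, vol: NuclearVolume, seed: int) -> pd.DataFrame:
    """Uniform random point catalog inside ``vol``.

    Returns a DataFrame with columns ``x_nm, y_nm, z_nm``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts = vol.sample(n, rng)
    return pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])


class PackingError(RuntimeError):
    """Raised when a hard-core catalog cannot be placed within the retry budget."""


class _HardCoreIndex:
    """Grid hash for incremental minimum-separation checks."""

    def __init__(self, min_sep: float):
        self.min_sep = min_sep
        self.cell = max(min_sep, 1.0)
        self.grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def ok(self, p: np.ndarray) -> bool:
        if self.min_sep <= 0:
            return True
        c = tuple((p // self.cell).astype(int))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.grid.get((c[0] + dx, c[1] + dy, c[2] + dz), ()):
                        if np.sum((p - q) ** 2) < self.min_sep**2:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        self.grid.setdefault(tuple((p // self.cell).astype(int)), []).append(p)


def gen_clustered_points(
    spec: ClusterSpec,
    vol: NuclearVolume,
    seed: int,
    max_oversampling: int = 100,
) -> pd.DataFrame:
    """Gaussian-clustered catalog with hard-core separation.

    Cluster centres are uniform in ``vol``; members are isotropic Gaussian
    offsets of S.D. ``spec.sigma_nm``.  Points falling outside the volume or
    closer than ``min_separation_nm`` to an existing point are resampled; after
    ``max_oversampling * n_points`` total attempts a :class:`PackingError` is
    raised rather than silently relaxing the constraints.

    Returns columns ``x_nm, y_nm, z_nm, cluster`` (ground-truth label); the
    cluster centres are attached as ``df.attrs["centers_nm"]``.
    """
    rng = np.random.default_rng(seed)
    centers = vol.sample(spec.n_clusters, rng)
    # even apportionment of points to clusters
    counts = np.full(spec.n_clusters, spec.n_points // spec.n_clusters)
    counts[: spec.n_points % spec.n_clusters] += 1

    index = _HardCoreIndex(spec.min_separation_nm)
    pts = np.empty((spec.n_points, 3))
    labels = np.empty(spec.n_points, dtype=int)
    budget = max_oversampling * spec.n_points
    i = 0
    for ci in range(spec.n_clusters):
        for _ in range(counts[ci]):
            while True:
                if budget <= 0:
                    raise PackingError(
                        "could not place clustered points under the "
                        "min-separation constraint; packing infeasible"
                    )
                budget -= 1
                p = centers[ci] + spec.sigma_nm * rng.standard_normal(3)
                if vol.contains(p[None, :])[0] and index.ok(p):
                    break
            index.add(p)
            pts[i] = p
            labels[i] = ci
            i += 1
    df = pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])
    df["cluster"] = labels
    df.attrs["centers_nm"] = centers
    return df


def gen_uniform_hardcore(
    n: int,
    vol: NuclearVolume,
    min_separation_nm: float,
    seed: int,
    max_oversampling: int = 100,
) -> pd.DataFrame:
    """Uniform random catalog with a hard-core minimum pairwise separation
    (random sequential placement with rejection)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    index = _HardCoreIndex(min_separation_nm)
    pts = np.empty((n, 3))
    budget = max_oversampling * n
    for i in range(n):
        while True:
            if budget <= 0:
                raise PackingError("uniform hard-core placement infeasible")
            budget -= 1
            p = vol.sample(1, rng)[0]
            if index.ok(p):
                break
        index.add(p)
        pts[i] = p
    return pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """Linked single-particle trajectories.

    ``data`` columns: ``track_id, frame, x_nm, y_nm, z_nm`` (``z_nm`` may be
    NaN for 2D data); ``dt_s`` is the frame interval.  ``labels`` optionally
    maps ``track_id`` to a ground-truth population index.
    """

    data: pd.DataFrame
    dt_s: float
    labels: pd.Series | None = None

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def ndim(self) -> int:
        z = self.data.get("z_nm")
        return 2 if z is None or z.isna().all() else 3

    def iter_tracks(self):
        """Yield ``(track_id, frames, xyz)`` with xyz of shape (n, ndim)."""
        cols = ["x_nm", "y_nm"] + (["z_nm"] if self.ndim == 3 else [])
        for tid, grp in self.data.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            yield tid, grp["frame"].to_numpy(), grp[cols].to_numpy(float)


@dataclass(frozen=True)
class TrackMixtureSpec:
    """Mixture of Brownian populations: ``populations`` is a sequence of
    ``(D_um2_s, fraction)``; fractions must sum to 1."""

    populations: Sequence[tuple[float, float]]
    dt_s: float
    n_tracks: int
    track_length: int
    loc_noise_sd_nm: float = 0.0

    def __post_init__(self):
        fr = np.array([f for _, f in self.populations])
        if not np.isclose(fr.sum(), 1.0):
            raise ValueError("population fractions must sum to 1")
        if any(d < 0 for d, _ in self.populations):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")


def gen_brownian_tracks(
    D_um2_s: float,
    dt_s: float,
    n_tracks: int,
    track_length: int,
    seed: int,
    ndim: int = 3,
    loc_noise_sd_nm: float = 0.0,
    start_nm: np.ndarray | None = None,
) -> TrackSet:
    """Pure Brownian trajectories: per-axis increments are Gaussian with
    variance ``2 * D * dt`` (in µm², converted to nm)."""
    if D_um2_s < 0 or dt_s <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    step_nm = np.sqrt(2.0 * D_um2_s * dt_s) * NM_PER_UM
    steps = step_nm * rng.standard_normal((n_tracks, track_length - 1, ndim))
    pos = np.zeros((n_tracks, track_length, ndim))
    pos[:, 1:] = np.cumsum(steps, axis=1)
    if start_nm is not None:
        pos += np.asarray(start_nm)[:, None, :]
    if loc_noise_sd_nm > 0:
        pos = pos + loc_noise_sd_nm * rng.standard_normal(pos.shape)
    frames = np.tile(np.arange(track_length), n_tracks)
    tids = np.repeat(np.arange(n_tracks), track_length)
    df = pd.DataFrame({"track_id": tids, "frame": frames})
    for ax, name in zip(range(ndim), ("x_nm", "y_nm", "z_nm")):
        df[name] = pos[:, :, ax].ravel()
    if ndim == 2:
        df["z_nm"] = np.nan
    return TrackSet(df, dt_s)


def gen_mixture_tracks(spec: TrackMixtureSpec, seed: int, ndim: int = 3) -> TrackSet:
    """Track mixture with per-track population labels retained.

    Track counts per population follow the requested fractions
    deterministically (largest-remainder apportionment), so the generated
    ground truth matches the spec exactly at any ``n_tracks``.
    """
    fractions = np.array([f for _, f in spec.populations])
    counts = np.floor(fractions * spec.n_tracks).astype(int)
    remainder = spec.n_tracks - counts.sum()
    order = np.argsort(-(fractions * spec.n_tracks - counts))
    counts[order[:remainder]] += 1

    frames, parts, labels = [], [], []
    next_id = 0
    for pop, ((D, _), cnt) in enumerate(zip(spec.populations, counts)):
        if cnt == 0:
            continue
        ts = gen_brownian_tracks(
            D, spec.dt_s, cnt, spec.track_length, seed + 7919 * pop, ndim=ndim,
            loc_noise_sd_nm=spec.loc_noise_sd_nm,
        )
        sub = ts.data.copy()
        sub["track_id"] += next_id
        for tid in range(next_id, next_id + cnt):
            labels.append((tid, pop))
        next_id += cnt
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)
    lab = pd.Series({tid: pop for tid, pop in labels}, name="population")
    return TrackSet(df, spec.dt_s, labels=lab)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def psf_model(
    coords_nm: tuple[np.ndarray, np.ndarray, np.ndarray],
    amplitude: float,
    x0: float,
    y0: float,
    z0: float,
    sigma_xy: float,
    sigma_z: float,
    background: float,
) -> np.ndarray:
    """3D Gaussian PSF plus constant background, evaluated at (x, y, z) in nm.

    The lateral S.D. is shared between x and y; the axial S.D. is separate.
    """
    x, y, z = coords_nm
    return (
        amplitude
        * np.exp(-((x - x0) ** 2) / (2 * sigma_xy**2))
        * np.exp(-((y - y0) ** 2) / (2 * sigma_xy**2))
        * np.exp(-((z - z0) ** 2) / (2 * sigma_z**2))
        + background
    )


def voxel_centers(shape: tuple[int, int, int], voxel_nm: tuple[float, float, float]):
    """Voxel-centre coordinate grids (x, y, z in nm) for a (nz, ny, nx) stack.

    Convention: the centre of voxel index i lies at (i + 0.5) * voxel size,
    origin at the stack corner.
    """
    nz, ny, nx = shape
    ax, ay, az = voxel_nm
    zi, yi, xi = np.meshgrid(
        (np.arange(nz) + 0.5) * az,
        (np.arange(ny) + 0.5) * ay,
        (np.arange(nx) + 0.5) * ax,
        indexing="ij",
    )
    return xi, yi, zi


def gen_spot_stack(
    positions_nm: np.ndarray,
    sigma_xy_nm: float,
    sigma_z_nm: float,
    amplitude: float,
    background: float,
    shape: tuple[int, int, int] = (15, 21, 21),
    voxel_nm: tuple[float, float, float] = (100.0, 100.0, 100.0),
    noise: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Render Gaussian spots into a (nz, ny, nx) photon-count stack.

    The expected count per voxel is the PSF model evaluated at the voxel
    centre; with ``noise=True`` the returned stack is Poisson-distributed
    around that expectation.  Overlapping spots add.
    """
    if amplitude < 0 or background < 0 or sigma_xy_nm <= 0 or sigma_z_nm <= 0:
        raise ValueError("PSF parameters must be non-negative (sigmas positive)")
    positions_nm = np.atleast_2d(positions_nm)
    xi, yi, zi = voxel_centers(shape, voxel_nm)
    expected = np.full(shape, float(background))
    for x0, y0, z0 in positions_nm:
        expected += psf_model((xi, yi, zi), amplitude, x0, y0, z0,
                              sigma_xy_nm, sigma_z_nm, 0.0)
    if not noise:
        return expected
    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(float)


# ---------------------------------------------------------------------------
# 2D intensity-map pairs
# ---------------------------------------------------------------------------

def gen_intensity_pair(
    colocalization: float,
    seed: int,
    grid: int = 100,
    pixel_nm: float = 160.0,
    nucleus_radius_nm: float = 6000.0,
    n_clusters: int = 100,
    points_per_cluster: int = 20,
    cluster_sigma_nm: float = 200.0,
    bandwidth_px: float = 2.0,
):
    """Two KDE intensity maps sharing a fraction of cluster centres.

    ``colocalization`` in [0, 1] is the fraction of cluster centres common to
    both channels; the remaining centres are drawn independently.  Returns
    ``(map1, map2, mask, truth)``; ``truth`` records the centre sets.

    The mask is the circular nucleus eroded by the density-kernel support:
    the KDE kernel spreads some weight beyond the point support, so pixels
    within a kernel scale of the rim systematically under-represent the local
    density, and masked-correlation analyses are stationary only inside the
    eroded region.
    """
    if not 0.0 <= colocalization <= 1.0:
        raise ValueError("colocalization must lie in [0, 1]")
    from .field_maps import IntensityMap, kde_intensity  # local import: no cycle at module load

    rng = np.random.default_rng(seed)
    field_nm = grid * pixel_nm
    center = np.array([field_nm / 2, field_nm / 2])

    # centres cover the whole disk so the mean density is flat across the
    # nucleus; members falling outside are resampled below
    def draw_centers(k):
        out = np.empty((0, 2))
        while out.shape[0] < k:
            c = rng.uniform(-1, 1, size=(4 * k, 2)) * nucleus_radius_nm
            c = c[np.linalg.norm(c, axis=1) <= nucleus_radius_nm]
            out = np.vstack([out, c])
        return center + out[:k]

    n_shared = int(round(colocalization * n_clusters))
    shared = draw_centers(n_shared)
    own1 = draw_centers(n_clusters - n_shared) if n_shared < n_clusters else np.empty((0, 2))
    own2 = draw_centers(n_clusters - n_shared) if n_shared < n_clusters else np.empty((0, 2))
    centers1 = np.vstack([shared, own1])
    centers2 = np.vstack([shared, own2])

    def render(centers):
        reps = np.repeat(centers, points_per_cluster, axis=0)
        pts = reps + cluster_sigma_nm * rng.standard_normal(reps.shape)
        bad = np.linalg.norm(pts - center, axis=1) > nucleus_radius_nm
        while bad.any():  # resample out-of-nucleus members around their centre
            pts[bad] = reps[bad] + cluster_sigma_nm * rng.standard_normal((bad.sum(), 2))
            bad = np.linalg.norm(pts - center, axis=1) > nucleus_radius_nm
        return kde_intensity(pts, grid=grid, bandwidth_px=bandwidth_px,
                             extent_nm=(0.0, field_nm, 0.0, field_nm))

    m1, m2 = render(centers1), render(centers2)
    yy, xx = np.meshgrid(
        (np.arange(grid) + 0.5) * pixel_nm, (np.arange(grid) + 0.5) * pixel_nm,
        indexing="ij",
    )
    disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= nucleus_radius_nm**2
    mask = binary_erosion(disk, iterations=int(np.ceil(1.5 * bandwidth_px)))
    truth = {
        "colocalization": colocalization,
        "centers1_nm": centers1,
        "centers2_nm": centers2,
        "n_shared": n_shared,
    }
    return m1, m2, mask, truth


# ---------------------------------------------------------------------------
# strand-specific peak lists (ChIP-exo style)
# ---------------------------------------------------------------------------

def gen_strand_peaks(
    n_sites: int,
    left_right_offset_bp: int,
    jitter_bp: int,
    chrom_sizes: dict[str, int],
    seed: int,
    peak_width_bp: int = 10,
    min_site_separation_bp: int = 200,
):
    """Paired forward/reverse peak lists around hidden binding sites.

    Each true site at position ``s`` emits a forward-strand peak whose
    midpoint is near ``s - offset/2`` and a reverse-strand peak near
    ``s + offset/2``; each midpoint is jittered independently by a uniform
    integer in ``[-jitter, jitter]``.  Sites on the same chromosome keep at
    least ``min_site_separation_bp`` between them (distinct binding sites are
    distinct loci; the truth table must stay unambiguous).  Returns
    ``(fwd, rev, truth)`` as BED-like DataFrames with 0-based half-open
    coordinates and a score column.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms])
    probs = sizes / sizes.sum()
    rows_f, rows_r, rows_t = [], [], []
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    half = left_right_offset_bp / 2.0
    for i in range(n_sites):
        for _ in range(1000):
            ci = rng.choice(len(chroms), p=probs)
            chrom, size = chroms[ci], sizes[ci]
            s = int(rng.integers(200, size - 200))
            if all(abs(s - q) >= min_site_separation_bp for q in placed[chrom]):
                break
        else:
            raise RuntimeError("could not place sites with the requested separation")
        placed[chrom].append(s)
        score = float(rng.gamma(4.0, 25.0))
        for strand, mid0, rows in (("+", s - half, rows_f), ("-", s + half, rows_r)):
            mid = int(round(mid0)) + (int(rng.integers(-jitter_bp, jitter_bp + 1))
                                      if jitter_bp > 0 else 0)
            start = mid - peak_width_bp // 2
            rows.append((chrom, start, start + peak_width_bp, f"site{i}", score, strand))
        rows_t.append((chrom, s, score))
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    fwd = pd.DataFrame(rows_f, columns=cols)
    rev = pd.DataFrame(rows_r, columns=cols)
    truth = pd.DataFrame(rows_t, columns=["chrom", "pos", "score"])
    return fwd, rev, truth


def gen_exo_reads(
    truth: pd.DataFrame,
    left_right_offset_bp: int,
    reads_per_site: int,
    read_length_bp: int,
    spread_bp: float,
    seed: int,
) -> pd.DataFrame:
    """Stranded reads whose 5'-ends pile up on either side of each true site.

    Forward reads start near ``site - offset/2``; reverse reads end near
    ``site + offset/2`` (their 5'-end).  Used to exercise the 5'-reduction and
    peak-calling plumbing against a known truth table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    half = left_right_offset_bp / 2.0
    for _, site in truth.iterrows():
        for strand in "+-":
            k = reads_per_site // 2
            jitter = np.round(spread_bp * rng.standard_normal(k)).astype(int)
            if strand == "+":
                starts = int(round(site.pos - half)) + jitter
                for st in starts:
                    rows.append((site.chrom, int(st), int(st) + read_length_bp, ".", 0, "+"))
            else:
                five = int(round(site.pos + half)) + jitter
                for fv in five:
                    rows.append((site.chrom, int(fv) - read_length_bp + 1, int(fv) + 1, ".", 0, "-"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
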