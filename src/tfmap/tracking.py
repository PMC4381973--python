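"""Trajectory linking, stable-binding-site extraction, and temporal profiles.

A "stable site" is a bound molecule detected across consecutive frames whose
every frame-to-frame step *and* end-to-end displacement stay below a
displacement bound (default 50 nm) for at least a duration cutoff (3 s for 3D
catalogs, 2 s for 2D maps).  Each qualifying track contributes a single site
at the mean of its localizations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import NM_PER_UM, TrackSet


def max_link_radius_nm(D_max_um2_s: float, dt_s: float, ndim: int) -> float:
    """Radial linking gate implied by a maximum diffusion coefficient:
    r_max = sqrt(2 * d * D_max * dt)."""
    return float(np.sqrt(2.0 * ndim * D_max_um2_s * dt_s) * NM_PER_UM)


def link_tracks(
    locs: pd.DataFrame,
    dt_s: float,
    D_max_um2_s: float | None = 0.05,
    r_max_nm: float | None = None,
    max_gap: int = 1,
) -> TrackSet:
    """Greedy nearest-neighbour frame-to-frame linking.

    Candidate (track, detection) pairs within the radial gate are assigned in
    order of increasing distance (ties broken by earliest indices); detections
    left unassigned start new tracks.  A track may bridge up to ``max_gap``
    empty frames.  The gate is either given directly (``r_max_nm``) or derived
    from ``D_max_um2_s`` via the dimensionality of the data.
    """
    cols = ["x_nm", "y_nm"]
    if "z_nm" in locs.columns and not locs["z_nm"].isna().all():
        cols.append("z_nm")
    if r_max_nm is None:
        if D_max_um2_s is None:
            raise ValueError("provide either D_max_um2_s or r_max_nm")
        r_max_nm = max_link_radius_nm(D_max_um2_s, dt_s, len(cols))

    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    track_of = np.full(len(locs), -1, dtype=int)
    active_pos: list[np.ndarray] = []   # last position per track
    active_frame: list[int] = []        # last frame per track
    n_tracks = 0

    for frame, idx in locs.groupby("frame").groups.items():
        idx = np.asarray(idx)
        pts = locs.loc[idx, cols].to_numpy(float)
        # candidate tracks: seen within the gap window
        cand = [t for t in range(n_tracks)
                if 1 <= frame - active_frame[t] <= max_gap + 1]
        pairs = []
        for t in cand:
            d = np.linalg.norm(pts - active_pos[t], axis=1)
            for j in np.nonzero(d <= r_max_nm)[0]:
                pairs.append((d[j], t, j))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t, used_j = set(), set()
        for d, t, j in pairs:
            if t in used_t or j in used_j:
                continue
            used_t.add(t)
            used_j.add(j)
            track_of[idx[j]] = t
            active_pos[t] = pts[j]
            active_frame[t] = frame
        for j in range(len(idx)):
            if j not in used_j:
                track_of[idx[j]] = n_tracks
                active_pos.append(pts[j])
                active_frame.append(frame)
                n_tracks += 1

    out = locs.copy()
    out["track_id"] = track_of
    return TrackSet(out, dt_s)


def stable_sites(
    tracks: TrackSet,
    max_disp_nm: float = 50.0,
    min_duration_s: float = 3.0,
    single_frame: str = "discard",
) -> pd.DataFrame:
    """Extract stable binding sites from a track set.

    A track qualifies when every frame-to-frame step and its end-to-end
    displacement are below ``max_disp_nm`` and its duration (number of frames
    times the frame interval) reaches ``min_duration_s``.  Each qualifying
    track is reduced to one site at the mean of its localizations.

    ``single_frame`` controls single-detection events: ``"discard"`` (fast
    acquisition) drops them; ``"bound"`` (slow acquisition, where moving
    molecules blur out) counts them as bound with one frame-interval duration.
    """
    if single_frame not in ("discard", "bound"):
        raise ValueError("single_frame must be 'discard' or 'bound'")
    rows = []
    for tid, frames, xyz in tracks.iter_tracks():
        n = len(frames)
        if n == 1 and single_frame == "discard":
            continue
        if n > 1:
            steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            end_to_end = np.linalg.norm(xyz[-1] - xyz[0])
            if steps.max() >= max_disp_nm or end_to_end >= max_disp_nm:
                continue
        duration = n * tracks.dt_s
        if duration < min_duration_s:
            continue
        mean = xyz.mean(axis=0)
        rows.append((tid, *mean, duration, int(frames[0]), n))
    cols = ["track_id", "x_nm", "y_nm"] + (["z_nm"] if tracks.ndim == 3 else []) + [
        "residence_s", "start_frame", "n_detections"]
    return pd.DataFrame(rows, columns=cols)


def residence_stats(sites: pd.DataFrame, bin_width_s: float = 3.0):
    """Residence-time histogram plus mean and standard error.

    Returns ``(hist, mean_s, sem_s)`` where ``hist`` has columns
    ``t_s`` (bin centre) and ``count``.
    """
    t = sites["residence_s"].to_numpy(float)
    if t.size == 0:
        raise ValueError("no sites")
    edges = np.arange(0.0, t.max() + 2 * bin_width_s, bin_width_s)
    counts, _ = np.histogram(t, bins=edges)
    hist = pd.DataFrame({"t_s": edges[:-1] + bin_width_s / 2, "count": counts})
    sem = float(t.std(ddof=1) / np.sqrt(t.size)) if t.size > 1 else 0.0
    return hist, float(t.mean()), sem


def detections_per_frame(locs: pd.DataFrame) -> pd.Series:
    """Number of localizations per frame over the full frame range."""
    counts = locs.groupby("frame").size()
    full = np.arange(locs["frame"].min(), locs["frame"].max() + 1)
    return counts.reindex(full, fill_value=0)


def canopy_clusters(points: np.ndarray, radius_nm: float = 400.0) -> np.ndarray:
    """Greedy canopy assignment: each point joins the first canopy centre
    within ``radius_nm``, else founds a new canopy at its own position."""
    points = np.atleast_2d(points)
    centers: list[np.ndarray] = []
    labels = np.empty(len(points), dtype=int)
    for i, p in enumerate(points):
        for ci, c in enumerate(centers):
            if np.linalg.norm(p - c) <= radius_nm:
                labels[i] = ci
                break
        else:
            centers.append(p)
            labels[i] = len(centers) - 1
    return labels


def arrival_cdf(
    sites: pd.DataFrame,
    cluster_regions: np.ndarray | None = None,
    canopy_radius_nm: float = 400.0,
) -> dict[int, pd.DataFrame]:
    """Cumulative arrival-time curve of stable sites per cluster region.

    Regions are either given as an array of region centres (each site is
    assigned to the nearest centre within the canopy radius; unassigned sites
    are dropped) or derived by canopy clustering of the site positions.
    Returns per-region DataFrames with columns ``start_frame`` and ``cdf``.
    """
    cols = [c for c in ("x_nm", "y_nm", "z_nm") if c in sites.columns]
    pts = sites[cols].to_numpy(float)
    if cluster_regions is None:
        labels = canopy_clusters(pts, canopy_radius_nm)
    else:
        centers = np.atleast_2d(cluster_regions)
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        labels = d.argmin(axis=1)
        labels[d.min(axis=1) > canopy_radius_nm] = -1
    out = {}
    frames = sites["start_frame"].to_numpy()
    for region in np.unique(labels):
        if region < 0:
            continue
        f = np.sort(frames[labels == region])
        cdf = np.arange(1, f.size + 1) / f.size
        out[int(region)] = pd.DataFrame({"start_frame": f, "cdf": cdf})
    return out
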