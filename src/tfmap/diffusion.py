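"""Regional diffusion analysis of single-particle tracks.

Tracks are partitioned by a binary region mask (without re-linking), each
fragment's diffusion coefficient is estimated from a linear MSD fit, and the
population structure (fast / slow / bound) is resolved by a Gaussian mixture
on log10 D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .synth import NM_PER_UM, TrackSet


def split_tracks_by_mask(
    tracks: TrackSet,
    mask: np.ndarray,
    pixel_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> tuple[TrackSet, TrackSet]:
    """Cut tracks into in-mask and out-of-mask fragments.

    Each detection is classified by the mask pixel under its (x, y) position;
    maximal runs of same-class consecutive detections become fragments with
    fresh ids (original id kept in ``source_track``).  Tracking itself is
    never redone, and every detection lands in exactly one fragment.
    Positions outside the mask grid count as out-of-mask.
    """
    mask = np.asarray(mask, bool)
    rows_in, rows_out = [], []
    next_id = [0, 0]
    for tid, frames, xyz in tracks.iter_tracks():
        col = ((xyz[:, 0] - origin_nm[0]) // pixel_nm).astype(int)
        row = ((xyz[:, 1] - origin_nm[1]) // pixel_nm).astype(int)
        ok = (row >= 0) & (row < mask.shape[0]) & (col >= 0) & (col < mask.shape[1])
        inside = np.zeros(len(frames), bool)
        inside[ok] = mask[row[ok], col[ok]]
        # split on state changes
        breaks = np.nonzero(np.diff(inside.astype(int)))[0] + 1
        for seg_idx, seg in enumerate(np.split(np.arange(len(frames)), breaks)):
            state = int(inside[seg[0]])
            rows = rows_in if state else rows_out
            fid = next_id[state]
            next_id[state] += 1
            for k in seg:
                rows.append((fid, tid, frames[k], *xyz[k]))
    cols = ["track_id", "source_track", "frame", "x_nm", "y_nm"]
    if tracks.ndim == 3:
        cols.append("z_nm")
    df_in = pd.DataFrame(rows_in, columns=cols)
    df_out = pd.DataFrame(rows_out, columns=cols)
    return TrackSet(df_in, tracks.dt_s), TrackSet(df_out, tracks.dt_s)


@dataclass
class MSDFit:
    """Linear MSD fit: ``D`` in µm²/s, fit R², number of MSD points used, and
    whether the fit met the acceptance threshold."""

    D_um2_s: float
    r_squared: float
    n_points: int
    accepted: bool


def msd_curve(xyz_nm: np.ndarray, dt_s: float, max_lag: int) -> np.ndarray:
    """Time-averaged MSD (µm²) at lags 1..max_lag for one trajectory."""
    xyz_um = np.asarray(xyz_nm, float) / NM_PER_UM
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        d = xyz_um[lag:] - xyz_um[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def estimate_D(
    xyz_nm: np.ndarray,
    dt_s: float,
    min_frames: int = 8,
    r2_min: float = 0.8,
    max_lag: int | None = None,
    max_lag_frac: float = 0.25,
) -> MSDFit:
    """Diffusion coefficient from a linear MSD-versus-lag fit.

    MSD(t) = 2 d D t with d the dimensionality of the coordinates; the fit
    (with free intercept, absorbing static localization error) uses lags
    1..max(4, frac*n).  Tracks shorter than ``min_frames`` raise; fits with
    R² below ``r2_min`` are returned with ``accepted=False`` and should be
    excluded from histograms.
    """
    xyz_nm = np.atleast_2d(np.asarray(xyz_nm, float))
    n = len(xyz_nm)
    if n < min_frames:
        raise ValueError(f"track shorter than {min_frames} frames")
    d = xyz_nm.shape[1]
    if max_lag is None:
        max_lag = min(n - 1, max(4, int(round(max_lag_frac * n))))
    msd = msd_curve(xyz_nm, dt_s, max_lag)
    t = np.arange(1, max_lag + 1) * dt_s
    slope, intercept = np.polyfit(t, msd, 1)
    pred = slope * t + intercept
    ss_res = np.sum((msd - pred) ** 2)
    ss_tot = np.sum((msd - msd.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    D = max(slope / (2.0 * d), 0.0)
    return MSDFit(D_um2_s=float(D), r_squared=float(r2), n_points=max_lag,
                  accepted=bool(r2 >= r2_min))


def estimate_D_per_track(tracks: TrackSet, min_frames: int = 8,
                         r2_min: float = 0.8) -> pd.DataFrame:
    """Apply :func:`estimate_D` to every sufficiently long track.

    Returns one row per eligible track: ``track_id, D_um2_s, r_squared,
    accepted``.
    """
    rows = []
    for tid, frames, xyz in tracks.iter_tracks():
        if len(frames) < min_frames or np.any(np.diff(frames) != 1):
            continue
        fit = estimate_D(xyz, tracks.dt_s, min_frames=min_frames, r2_min=r2_min)
        rows.append((tid, fit.D_um2_s, fit.r_squared, fit.accepted))
    return pd.DataFrame(rows, columns=["track_id", "D_um2_s", "r_squared", "accepted"])


@dataclass
class MixtureFit:
    """Gaussian mixture over log10 D.

    ``components`` is a list of ``(D_um2_s, sd_log10, weight)`` sorted by
    descending D (fast first); ``bic`` supports model-order comparison;
    ``degenerate`` flags components with vanishing weight.
    """

    components: list[tuple[float, float, float]]
    k: int
    bic: float
    degenerate: bool


def d_histogram_mixture(
    D_values: np.ndarray, k: int = 2, seed: int = 0, d_floor: float = 1e-4
) -> MixtureFit:
    """Fit ``k`` Gaussian components to the log10 D histogram.

    Diffusion-coefficient histograms of nuclear factors span two decades
    (bound ~0.02 µm²/s versus free ~1-3 µm²/s), so the mixture is fitted in
    log space and component means are reported back-transformed.  Values at or
    below ``d_floor`` are clamped to it before taking logs.
    """
    D = np.asarray(D_values, float)
    D = D[np.isfinite(D)]
    if D.size < 5 * k:
        raise ValueError("too few D values for the requested mixture order")
    logd = np.log10(np.clip(D, d_floor, None))[:, None]
    gm = GaussianMixture(n_components=k, n_init=5, random_state=seed)
    gm.fit(logd)
    comps = [
        (float(10 ** gm.means_[i, 0]), float(np.sqrt(gm.covariances_[i, 0, 0])),
         float(gm.weights_[i]))
        for i in range(k)
    ]
    comps.sort(key=lambda c: -c[0])
    degenerate = any(w < 0.02 for _, _, w in comps)
    return MixtureFit(components=comps, k=k, bic=float(gm.bic(logd)),
                      degenerate=degenerate)
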