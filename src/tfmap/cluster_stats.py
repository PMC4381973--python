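"""3D clustering statistics for stable-binding-site catalogs.

Implements the neighbour-density (canopy) count, the random-catalog
pair-correlation estimator g(r), and the fluctuation-model fit that separates
true clustering (an exponential spatial correlation of amplitude A and range
epsilon) from apparent correlation induced by the finite localization spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .synth import NuclearVolume


def neighbor_density(points_nm: np.ndarray | pd.DataFrame,
                     radius_nm: float = 400.0) -> np.ndarray:
    """Number of other points within ``radius_nm`` of each point
    (canopy neighbour count used for density heat maps)."""
    if isinstance(points_nm, pd.DataFrame):
        points_nm = points_nm[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    points_nm = np.atleast_2d(points_nm)
    tree = cKDTree(points_nm)
    counts = tree.query_ball_point(points_nm, radius_nm, return_length=True)
    return counts - 1  # exclude self


@dataclass
class CorrelationCurve:
    """Binned pair-correlation estimate.

    ``r_nm`` are bin centres (bin k spans ``(k*dr, (k+1)*dr]``); ``g`` is NaN
    where the random catalog produced no pairs.  ``dd``/``rr`` are the raw
    non-redundant pair counts, ``n_data``/``n_random`` the catalog sizes.
    """

    r_nm: np.ndarray
    dr_nm: float
    g: np.ndarray
    dd: np.ndarray
    rr: np.ndarray
    n_data: int
    n_random: int
    g_err: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"r_nm": self.r_nm, "g": self.g,
                           "dd": self.dd, "rr": self.rr})
        if self.g_err is not None:
            df["g_err"] = self.g_err
        return df


def _pair_counts(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Non-redundant pair counts per bin; bins are (lo, hi] on the edge grid."""
    tree = cKDTree(points)
    cum = tree.count_neighbors(tree, edges).astype(float)
    cum = (cum - len(points)) / 2.0  # remove self pairs, count each pair once
    return np.diff(cum)


def pair_correlation_3d(
    points_nm: np.ndarray | pd.DataFrame,
    dr_nm: float = 50.0,
    r_max_nm: float = 1500.0,
    random_factor: int = 10,
    volume: NuclearVolume | str = "hull",
    seed: int = 0,
    n_random_draws: int = 1,
) -> CorrelationCurve:
    """Random-catalog pair-correlation estimator.

    g(r) = [NR (NR - 1)] / [N (N - 1)] * DD(r) / RR(r)

    where DD and RR are non-redundant pair counts in separation bins of width
    ``dr_nm`` (centres at multiples of ``dr_nm``) for the data catalog and a
    uniform random catalog of ``random_factor`` times the size, drawn in the
    same volume.  By default the volume is the 3D convex hull of the data;
    pass a :class:`~tfmap.synth.NuclearVolume` to declare the geometry
    explicitly (e.g. a sphere for spherical synthetic data, avoiding hull bias
    at low n).

    With ``n_random_draws > 1`` the random catalog is re-drawn and ``g_err``
    reports the S.D. of g across draws.
    """
    if isinstance(points_nm, pd.DataFrame):
        points_nm = points_nm[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    points_nm = np.asarray(points_nm, dtype=float)
    n = len(points_nm)
    if n < 2:
        raise ValueError("need at least 2 points")
    if volume == "hull":
        volume = NuclearVolume(shape="hull", hull_points_nm=points_nm)
    elif not isinstance(volume, NuclearVolume):
        raise ValueError("volume must be 'hull' or a NuclearVolume")

    n_bins = int(np.round(r_max_nm / dr_nm))
    edges = np.arange(n_bins + 1) * dr_nm
    centers = edges[:-1] + dr_nm / 2
    dd = _pair_counts(points_nm, edges)

    rng = np.random.default_rng(seed)
    nr = random_factor * n
    norm = (nr * (nr - 1)) / (n * (n - 1))
    gs = []
    rr_last = None
    for _ in range(max(1, n_random_draws)):
        randoms = volume.sample(nr, rng)
        rr = _pair_counts(randoms, edges)
        rr_last = rr
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(rr > 0, norm * dd / np.where(rr > 0, rr, 1), np.nan)
        gs.append(g)
    gs = np.array(gs)
    g_mean = gs.mean(axis=0)
    g_err = gs.std(axis=0, ddof=1) if len(gs) > 1 else None
    return CorrelationCurve(r_nm=centers, dr_nm=dr_nm, g=g_mean, dd=dd,
                            rr=rr_last, n_data=n, n_random=nr, g_err=g_err)


# ---------------------------------------------------------------------------
# fluctuation model
# ---------------------------------------------------------------------------

def effective_psf_sd(s_bar_nm: float, a_bar_nm: float = 0.0) -> float:
    """Effective localization spread: sigma_bar^2 = s_bar^2 + a_bar^2 / 12,
    combining the mean PSF S.D. with the voxel quantisation term."""
    return float(np.sqrt(s_bar_nm**2 + a_bar_nm**2 / 12.0))


def _radial_gaussian_convolve(f, r_eval: np.ndarray, sigma_bar: float,
                              s_max: float, ds: float) -> np.ndarray:
    """3D isotropic convolution of a radial profile with the PSF-pair kernel.

    The kernel is the normalised 3D Gaussian of per-axis variance
    ``2 * sigma_bar**2`` (the pair-correlation of a Gaussian localization
    spread of S.D. ``sigma_bar``).  For radial f and Gaussian kernel the 3D
    convolution reduces to a 1D integral:

        (f * K)(r) = 1 / (r sqrt(2 pi v)) *
                     Int_0^inf s f(s) [e^{-(r-s)^2/2v} - e^{-(r+s)^2/2v}] ds

    with v = 2 sigma_bar^2, evaluated here by trapezoidal quadrature.
    """
    v = 2.0 * sigma_bar**2
    s = np.arange(ds / 2, s_max, ds)
    fs = f(s) * s
    r = np.asarray(r_eval, dtype=float)[:, None]
    kern = (np.exp(-((r - s[None, :]) ** 2) / (2 * v))
            - np.exp(-((r + s[None, :]) ** 2) / (2 * v)))
    integral = (fs[None, :] * kern).sum(axis=1) * ds
    return integral / (r[:, 0] * np.sqrt(2 * np.pi * v))


def fluctuation_forward(r_nm: np.ndarray, amplitude: float, range_nm: float,
                        sigma_bar_nm: float) -> np.ndarray:
    """Model pair-correlation of Gaussian-blurred exponential clustering:
    (A exp(-r/eps) + 1) convolved with the PSF pair kernel.

    The kernel integrates to one, so the flat baseline is preserved and only
    the exponential term needs the numerical convolution.
    """
    r_nm = np.asarray(r_nm, dtype=float)
    if sigma_bar_nm <= 0:
        return amplitude * np.exp(-r_nm / range_nm) + 1.0
    ds = min(sigma_bar_nm / 4.0, range_nm / 10.0, 5.0)
    s_max = r_nm.max() + 8.0 * sigma_bar_nm + 3.0 * range_nm
    conv = _radial_gaussian_convolve(
        lambda s: np.exp(-s / range_nm), r_nm, sigma_bar_nm, s_max, ds)
    return amplitude * conv + 1.0


@dataclass
class FluctuationFit:
    """Fitted fluctuation amplitude A (density enrichment in clusters relative
    to the global mean) and range epsilon (proportional to cluster size)."""

    amplitude: float
    range_nm: float
    sigma_bar_nm: float
    amplitude_ci: tuple[float, float]
    range_ci: tuple[float, float]
    converged: bool


def fit_fluctuation_model(
    curve: CorrelationCurve,
    s_bar_nm: float,
    a_bar_nm: float = 0.0,
    psf_convolution: bool = True,
) -> FluctuationFit:
    """Fit the clustering amplitude and range to a measured g(r).

    The model is ``(A exp(-r/eps) + 1)`` convolved with the localization-spread
    pair kernel of S.D. ``sigma_bar`` (trust-region least squares).  The
    repeat-appearance ("stochastic") term is taken as zero: stable sites are
    counted once, at the average of their localizations.  For simulated
    catalogs with no localization blur pass ``psf_convolution=False`` to fit
    the exponential directly.

    Bins with undefined g are ignored.  A flat curve pins A at 0.
    """
    valid = np.isfinite(curve.g)
    if valid.sum() < 10:
        raise ValueError("need at least 10 defined bins")
    r = curve.r_nm[valid]
    g = curve.g[valid]
    sigma_bar = effective_psf_sd(s_bar_nm, a_bar_nm) if psf_convolution else 0.0

    def model(r_, A, eps):
        return fluctuation_forward(r_, A, eps, sigma_bar)

    a0 = max(float(g.max() - 1.0), 1e-3)
    p0 = (a0, max(3 * curve.dr_nm, 2 * sigma_bar + 1))
    try:
        popt, pcov = curve_fit(
            model, r, g, p0=p0, bounds=([0.0, 1.0], [np.inf, 1e6]),
            method="trf", maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(perr)))
    except RuntimeError:
        popt, perr, converged = np.array(p0), np.array([np.inf, np.inf]), False
    A, eps = popt
    return FluctuationFit(
        amplitude=float(A), range_nm=float(eps), sigma_bar_nm=sigma_bar,
        amplitude_ci=(float(A - 1.96 * perr[0]), float(A + 1.96 * perr[0])),
        range_ci=(float(eps - 1.96 * perr[1]), float(eps + 1.96 * perr[1])),
        converged=converged,
    )
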