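"""2D intensity maps, nucleus masks, and masked FFT correlation analysis.

Intensity maps are kernel-density renderings of localization positions (or
normalised wide-field channels).  The masked, FFT-based pair cross-correlation
normalises the raw image correlation by the mask autocorrelation and the mean
surface densities, so that c(r) = 1 signals no spatial relationship at
separation r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, ifft2, fftshift
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr


@dataclass
class IntensityMap:
    """Non-negative intensity grid with physical pixel size (nm)."""

    data: np.ndarray
    pixel_nm: float

    def density_in(self, mask: np.ndarray) -> float:
        """Mean intensity over the mask (surface density rho)."""
        return float(self.data[mask].mean())


def kde_intensity(
    points_xy_nm: np.ndarray,
    grid: int = 100,
    bandwidth_px: float = 2.0,
    extent_nm: tuple[float, float, float, float] | None = None,
) -> IntensityMap:
    """Gaussian kernel density map of 2D points on a ``grid x grid`` matrix.

    The bandwidth is expressed in grid units (default 2), matching density
    estimation on an arbitrary-unit 100 x 100 matrix that is subsequently
    rescaled to the physical image size.  The returned map integrates
    (sums) to 1 over the grid.

    ``extent_nm`` is (x0, x1, y0, y1); by default the point bounding box.
    """
    points_xy_nm = np.atleast_2d(points_xy_nm)
    if len(points_xy_nm) < 2:
        raise ValueError("need at least 2 points for a density map")
    if extent_nm is None:
        x0, y0 = points_xy_nm.min(axis=0)
        x1, y1 = points_xy_nm.max(axis=0)
    else:
        x0, x1, y0, y1 = extent_nm
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate extent")
    hist, _, _ = np.histogram2d(
        points_xy_nm[:, 1], points_xy_nm[:, 0], bins=grid,
        range=[[y0, y1], [x0, x1]],
    )
    smooth = gaussian_filter(hist, sigma=bandwidth_px, mode="constant")
    total = smooth.sum()
    if total > 0:
        smooth = smooth / total
    pixel_nm = (x1 - x0) / grid
    return IntensityMap(smooth, pixel_nm)


def make_mask(imap: IntensityMap | np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Binary region mask: max-normalised intensity >= ``threshold``."""
    data = imap.data if isinstance(imap, IntensityMap) else np.asarray(imap, float)
    peak = data.max()
    if peak <= 0:
        raise ValueError("cannot threshold an all-zero map")
    return data / peak >= threshold


def normalize_channel(
    image: np.ndarray, background_percentile: float = 10.0
) -> np.ndarray:
    """Background-subtracted, max-normalised channel in [0, 1].

    The background level is estimated as a low percentile of the pixel
    intensities (robust when signal occupies a minority of pixels), subtracted
    and clipped at zero; the result is divided by its maximum.
    """
    img = np.asarray(image, dtype=float)
    bg = np.percentile(img, background_percentile)
    out = np.clip(img - bg, 0.0, None)
    peak = out.max()
    return out / peak if peak > 0 else out


# ---------------------------------------------------------------------------
# masked FFT correlation
# ---------------------------------------------------------------------------

def cross_correlation_2d(
    I1: np.ndarray, I2: np.ndarray, mask: np.ndarray, min_overlap: float = 0.5
):
    """Masked normalised cross-correlation as a full 2D lag map.

    c(dr) = Re{ IFFT( FFT(I1) conj(FFT(I2)) ) } / (rho1 rho2 N(dr)),
    N(dr) = Re{ IFFT( |FFT(mask)|^2 ) },

    where images are zeroed outside the mask and rho1/rho2 are mean
    intensities inside it.  Arrays are zero-padded to twice their linear size
    so wrap-around never mixes opposite edges; N(dr) counts the overlapping
    mask pixels at each lag and lags with fewer than ``min_overlap`` pixels
    are returned NaN.

    Returns ``(c, n_overlap)``, both fftshifted so zero lag sits at
    ``(rows//2, cols//2)`` of the padded shape.
    """
    I1 = np.asarray(I1, float)
    I2 = np.asarray(I2, float)
    mask = np.asarray(mask, bool)
    if not (I1.shape == I2.shape == mask.shape):
        raise ValueError("images and mask must share a shape")
    if not mask.any():
        raise ValueError("empty mask")
    rho1 = I1[mask].mean()
    rho2 = I2[mask].mean()
    if rho1 <= 0 or rho2 <= 0:
        raise ValueError("zero mean intensity inside the mask")

    pad = tuple((0, s) for s in mask.shape)  # pad to 2x linear size
    J1 = np.pad(np.where(mask, I1, 0.0), pad)
    J2 = np.pad(np.where(mask, I2, 0.0), pad)
    M = np.pad(mask.astype(float), pad)

    raw = np.real(ifft2(fft2(J1) * np.conj(fft2(J2))))
    n_overlap = np.real(ifft2(np.abs(fft2(M)) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = raw / (rho1 * rho2 * n_overlap)
    c[n_overlap < min_overlap] = np.nan
    return fftshift(c), fftshift(n_overlap)


def radial_average(c: np.ndarray, weights: np.ndarray | None = None,
                   dr_px: float = 1.0):
    """Angular average of a centred 2D lag map into radial bins of width
    ``dr_px`` pixels.  Returns ``(r_px, values)``; bins without finite pixels
    are NaN."""
    rows, cols = c.shape
    yy, xx = np.indices(c.shape)
    r = np.hypot(yy - rows // 2, xx - cols // 2)
    bins = np.floor(r / dr_px + 0.5).astype(int)  # bin k covers r in [k-.5, k+.5)*dr
    nbins = bins.max() + 1
    finite = np.isfinite(c)
    w = np.ones_like(c) if weights is None else np.asarray(weights, float)
    num = np.bincount(bins[finite], (c * w)[finite], minlength=nbins)
    den = np.bincount(bins[finite], w[finite], minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(den > 0, num / den, np.nan)
    return np.arange(nbins) * dr_px, vals


def cross_correlation(
    I1: IntensityMap | np.ndarray,
    I2: IntensityMap | np.ndarray,
    mask: np.ndarray,
    pixel_nm: float | None = None,
    dr_px: float = 1.0,
):
    """Angularly averaged masked cross-correlation curve.

    Returns ``(r_nm, c)``.  Values are reliable only beyond one pixel
    (the kernel scale of the density maps); the zero-lag bin is included for
    completeness.  Pass the two maps as :class:`IntensityMap` (pixel size
    taken from the first) or as arrays with an explicit ``pixel_nm``.
    Autocorrelation is the ``I2 is I1`` case.
    """
    if isinstance(I1, IntensityMap):
        pixel_nm = I1.pixel_nm if pixel_nm is None else pixel_nm
        I1 = I1.data
    if isinstance(I2, IntensityMap):
        I2 = I2.data
    if pixel_nm is None:
        raise ValueError("pixel_nm required when passing bare arrays")
    c2d, n_ov = cross_correlation_2d(I1, I2, mask)
    r_px, vals = radial_average(c2d, weights=n_ov, dr_px=dr_px)
    return r_px * pixel_nm, vals


def permute_within_mask(imap: IntensityMap | np.ndarray, mask: np.ndarray,
                        seed: int):
    """Spatial permutation null: pixel values inside the mask are randomly
    shuffled; pixels outside are untouched.  Preserves the in-mask histogram
    and surface density exactly."""
    data = imap.data if isinstance(imap, IntensityMap) else np.asarray(imap, float)
    rng = np.random.default_rng(seed)
    out = data.copy()
    vals = out[mask]
    out[mask] = rng.permutation(vals)
    if isinstance(imap, IntensityMap):
        return IntensityMap(out, imap.pixel_nm)
    return out


# ---------------------------------------------------------------------------
# pixel-wise statistics
# ---------------------------------------------------------------------------

def pixel_correlation(
    I1: np.ndarray, I2: np.ndarray, mask: np.ndarray,
    background_gate: float = 0.2,
):
    """Pixel-intensity Pearson correlation between two channels.

    Both channels are max-normalised inside the mask; pixels where *both*
    fall below ``background_gate`` are treated as background and excluded
    from the correlation.  Also reported: the fraction of in-mask pixels per
    intensity quadrant (low/high in each channel at the same gate).
    """
    I1 = np.asarray(I1, float)
    I2 = np.asarray(I2, float)
    mask = np.asarray(mask, bool)
    a = I1[mask] / I1[mask].max()
    b = I2[mask] / I2[mask].max()
    background = (a < background_gate) & (b < background_gate)
    if (~background).sum() < 3:
        raise ValueError("too few non-background pixels")
    rho = float(pearsonr(a[~background], b[~background]).statistic)
    n = a.size
    quadrants = {
        "low_low": float(background.sum() / n),
        "high_low": float(((a >= background_gate) & (b < background_gate)).sum() / n),
        "low_high": float(((a < background_gate) & (b >= background_gate)).sum() / n),
        "high_high": float(((a >= background_gate) & (b >= background_gate)).sum() / n),
    }
    return rho, quadrants


def rfi(image: np.ndarray, region_mask: np.ndarray, surround_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Relative fluorescence intensity of a region versus its surroundings:

    RFI = (I_region - I_background) / (I_surround - I_background)

    with I the mean gray intensity over each mask.  RFI = 1 means the region
    is as bright as its surroundings; 0 means it is at background level.
    """
    img = np.asarray(image, float)
    i_reg = img[np.asarray(region_mask, bool)].mean()
    i_sur = img[np.asarray(surround_mask, bool)].mean()
    i_bg = img[np.asarray(background_mask, bool)].mean()
    denom = i_sur - i_bg
    if denom == 0:
        raise ValueError("surround and background intensities coincide")
    return float((i_reg - i_bg) / denom)


def register_by_outline(imageA: np.ndarray, imageB: np.ndarray,
                        threshold: float = 0.2) -> tuple[int, int]:
    """Rigid translation aligning two nucleus outlines.

    Both images are thresholded into binary masks (after max-normalisation)
    and the integer pixel shift maximising their overlap is located via the
    cross-correlation peak.  Returns ``(dy, dx)`` such that shifting B by it
    aligns B onto A.
    """
    from skimage.registration import phase_cross_correlation

    mA = make_mask(np.asarray(imageA, float), threshold).astype(float)
    mB = make_mask(np.asarray(imageB, float), threshold).astype(float)
    shift, _, _ = phase_cross_correlation(mA, mB, upsample_factor=1)
    return int(round(shift[0])), int(round(shift[1]))
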