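"""Quantification of paired No-AO / AO data.

The instrument's standard readouts: per-pixel AO/No-AO ratio maps of
maximum-intensity projections, radially averaged ratio profiles and the
effective correction radius (largest radius where the mean ratio stays
≥ 1), line/axial profiles and their FWHM, spatial-frequency content,
background-subtracted signal-gain factors, and calcium ΔF/F with a
percentile baseline (ΔF/F = 100·(F − F₀)/F₀ with F₀ the 10th percentile
of the raw trace over the chosen window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ImageStack
from .zernike import GeometryError

__all__ = [
    "RatioMap",
    "RadialProfile",
    "DffTrace",
    "ratio_map",
    "radial_profile",
    "frequency_map",
    "bandwidth_radius",
    "signal_gain",
    "dff",
]


@dataclass
class RatioMap:
    """Per-pixel AO / No-AO intensity fold-change map."""

    map: np.ndarray
    px_um: float
    epsilon: float
    smoothing_sigma_px: float


@dataclass
class RadialProfile:
    """Radially averaged ratio about the wavefront-sensing site."""

    center_um: tuple[float, float]
    radii_um: np.ndarray  # bin centers, strictly increasing
    mean_ratio: np.ndarray
    effective_radius_um: float


@dataclass
class DffTrace:
    """Percent ΔF/F trace with its percentile baseline."""

    f: np.ndarray
    f0: float
    dff: np.ndarray
    baseline_window: slice
    percentile: float


def _as_mip(img) -> tuple[np.ndarray, float]:
    if isinstance(img, ImageStack):
        return img.mip().astype(float), img.px_um
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        return a.max(axis=0), 1.0
    return a, 1.0


def ratio_map(
    ao,
    noao,
    epsilon: float | None = None,
    sigma_px: float = 1.0,
) -> RatioMap:
    """AO / No-AO pixel ratio map on maximum-intensity projections.

    Both inputs are optionally Gaussian-smoothed (sigma_px); the
    denominator is floored at epsilon (default 1% of the No-AO maximum) so
    empty background does not explode the ratio.  Inputs must be
    co-registered and the same shape.
    """
    a, px = _as_mip(ao)
    b, _ = _as_mip(noao)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch {a.shape} vs {b.shape}")
    if sigma_px > 0:
        a = gaussian_filter(a, sigma_px)
        b = gaussian_filter(b, sigma_px)
    if epsilon is None:
        epsilon = 0.01 * float(b.max()) if b.max() > 0 else 1e-12
    m = a / np.maximum(b, epsilon)
    return RatioMap(m, px, epsilon, sigma_px)


def radial_profile(
    rm: RatioMap,
    center_um: tuple[float, float] = (0.0, 0.0),
    bin_um: float = 5.0,
) -> RadialProfile:
    """Annulus means of a ratio map about a center, plus effective radius.

    center_um is measured from the map center (the wavefront-sensing site
    in the standard workflow).  The effective radius is the largest radius
    with mean ratio ≥ 1 before the first sustained dip (two consecutive
    sub-1 bins); a profile that never dips sustains to the last bin.
    """
    ny, nx = rm.map.shape
    px = rm.px_um
    cx = nx / 2.0 + center_um[0] / px
    cy = ny / 2.0 + center_um[1] / px
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"center {center_um} outside the map")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_um = np.hypot((xx + 0.5 - cx) * px, (yy + 0.5 - cy) * px)
    n_bins = int(np.ceil(r_um.max() / bin_um))
    idx = np.minimum((r_um / bin_um).astype(int), n_bins - 1)
    sums = np.bincount(idx.ravel(), weights=rm.map.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    mean = sums / np.maximum(counts, 1)
    radii = (np.arange(n_bins) + 0.5) * bin_um
    below = mean < 1.0
    eff = radii[-1]
    for i in range(n_bins - 1):
        if below[i] and below[i + 1]:
            eff = radii[i - 1] if i > 0 else 0.0
            break
    else:
        # single trailing sub-1 bin still ends the supported range
        if below[-1]:
            eff = radii[-2] if n_bins > 1 else 0.0
    return RadialProfile(center_um, radii, mean, float(eff))


def frequency_map(img: np.ndarray) -> np.ndarray:
    """Centered log-magnitude of the 2D DFT of a single image plane."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("frequency_map expects a single 2D plane")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(a)))
    return np.log1p(mag)


def bandwidth_radius(img: np.ndarray, energy_frac: float = 0.9) -> float:
    """Radius (in frequency pixels) enclosing a fraction of off-DC spectral energy.

    The summary used to compare AO vs No-AO spatial-frequency content: a
    sharper image concentrates more energy at high frequency, giving a
    larger radius for the same enclosed fraction.
    """
    a = np.asarray(img, dtype=float)
    power = np.abs(np.fft.fftshift(np.fft.fft2(a))) ** 2
    ny, nx = power.shape
    cy, cx = ny // 2, nx // 2
    power = power.copy()
    power[cy, cx] = 0.0  # drop DC
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - cx, yy - cy)
    order = np.argsort(r.ravel())
    cum = np.cumsum(power.ravel()[order])
    if cum[-1] <= 0:
        return 0.0
    k = int(np.searchsorted(cum, energy_frac * cum[-1]))
    return float(r.ravel()[order][min(k, len(cum) - 1)])


def signal_gain(ao, noao, roi: np.ndarray) -> float:
    """Fold-change of background-subtracted mean ROI intensity.

    Background per image = the mode of its intensity histogram (the empty
    retina between structures).  roi is a boolean mask on the MIP.
    """
    a, _ = _as_mip(ao)
    b, _ = _as_mip(noao)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    num = a[roi].mean() - _histogram_mode(a)
    den = b[roi].mean() - _histogram_mode(b)
    if den <= 0:
        raise ZeroDivisionError("No-AO ROI signal does not exceed background")
    return float(num / den)


def _histogram_mode(img: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(img, bins=bins)
    i = int(hist.argmax())
    return 0.5 * (edges[i] + edges[i + 1])


def dff(
    f: np.ndarray,
    percentile: float = 10.0,
    window: slice | None = None,
) -> DffTrace:
    """Percent ΔF/F of a fluorescence trace with a percentile baseline.

    F₀ is the given percentile of the raw trace over the baseline window
    (default: the whole trace; the standard workflow passes the treatment
    epoch), and ΔF/F(t) = 100·(F(t) − F₀)/F₀.  Invariant under
    multiplicative rescaling of F.
    """
    f = np.asarray(f, dtype=float)
    if window is None:
        window = slice(0, len(f))
    seg = f[window]
    if seg.size == 0:
        raise ValueError("empty baseline window")
    f0 = float(np.percentile(seg, percentile))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0 = {f0}")
    return DffTrace(f, f0, 100.0 * (f - f0) / f0, window, percentile)
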