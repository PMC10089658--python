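"""Shack–Hartmann wavefront sensor simulation.

A lenslet array segments the pupil into subapertures; each lenslet focuses
its patch of the wavefront to a spot on a camera, and the spot's
displacement from its reference position is proportional to the mean
wavefront gradient over the subaperture.  This module renders such camera
frames (Gaussian spot model, optional Poisson photon noise), finds spot
centroids, and converts centroid displacements to a slope field.

Units: wavefront slopes are µm of optical path per normalized pupil unit;
``focal_px`` converts them to pixels of spot displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .zernike import GeometryError, PupilGrid, Wavefront

__all__ = [
    "LensletArray",
    "SHFrame",
    "SlopeField",
    "render_sh_frame",
    "find_centroids",
    "slopes_from_centroids",
    "reference_frame",
    "mean_gradient_field",
]


@dataclass(frozen=True)
class LensletArray:
    """Lenslet-array geometry and spot model.

    focal_px is chosen so 1 µm rms of defocus (max gradient 4√3 µm/unit at
    the pupil rim) displaces the rim spots by about 3 px.
    """

    n_across: int = 16
    focal_px: float = 3.0 / (4.0 * np.sqrt(3.0))
    spot_sigma_px: float = 1.5
    win_px: int = 16
    min_fill: float = 0.5  # min in-mask area fraction for an illuminated subap

    def __post_init__(self) -> None:
        if self.n_across < 4:
            raise ValueError("n_across must be >= 4")
        if self.win_px < 8:
            raise ValueError("win_px must be >= 8")

    @property
    def frame_px(self) -> int:
        return self.n_across * self.win_px

    def subap_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized pupil coordinates of subaperture centers (1D per axis)."""
        edges = np.linspace(-1.0, 1.0, self.n_across + 1)
        c = 0.5 * (edges[:-1] + edges[1:])
        return np.meshgrid(c, c, indexing="xy")


@dataclass
class SHFrame:
    """A simulated Shack–Hartmann camera frame with per-subaperture metadata.

    centroids / reference are (n_across, n_across, 2) in frame pixels
    (x, y); valid marks subapertures carrying a usable spot.
    """

    image: np.ndarray
    centroids: np.ndarray
    reference: np.ndarray
    valid: np.ndarray
    arr: LensletArray
    photon_scale: float = 0.0


@dataclass
class SlopeField:
    """Per-subaperture mean wavefront gradient (µm per normalized unit)."""

    sx: np.ndarray
    sy: np.ndarray
    valid: np.ndarray
    arr: LensletArray

    def rms(self) -> float:
        v = self.valid
        return float(np.sqrt(np.mean(self.sx[v] ** 2 + self.sy[v] ** 2)))


def _subap_fill(arr: LensletArray, grid: PupilGrid) -> np.ndarray:
    """In-mask area fraction of each subaperture."""
    mask = grid.mask
    idx = _bin_index(grid, arr)
    fill = np.zeros((arr.n_across, arr.n_across))
    for jy in range(arr.n_across):
        rows = idx == jy
        for jx in range(arr.n_across):
            cols = idx == jx
            block = mask[np.ix_(rows, cols)]
            fill[jy, jx] = block.mean()
    return fill


def _bin_index(grid: PupilGrid, arr: LensletArray) -> np.ndarray:
    """Subaperture bin of each grid sample along one axis, by coordinate.

    Binning by sample coordinate (not array index) keeps cell boundaries on
    the subaperture edges for any grid/lenslet size ratio, so cell means
    are centered on the subaperture centers.
    """
    c = np.linspace(-1.0, 1.0, grid.n_samples)
    idx = np.floor((c + 1.0) / 2.0 * arr.n_across).astype(int)
    return np.clip(idx, 0, arr.n_across - 1)


def mean_gradient_field(w: Wavefront, arr: LensletArray) -> SlopeField:
    """Mean wavefront gradient over each illuminated subaperture.

    This is the forward measurement model: gradients of the phase map
    (central differences in normalized coordinates) averaged over the
    in-mask samples of each subaperture cell.
    """
    grid = w.grid
    n = grid.n_samples
    h = grid.sample_spacing
    gy, gx = np.gradient(w.phase, h)
    mask = grid.mask
    idx = _bin_index(grid, arr)
    sx = np.zeros((arr.n_across, arr.n_across))
    sy = np.zeros_like(sx)
    valid = np.zeros(sx.shape, dtype=bool)
    for jy in range(arr.n_across):
        rows = idx == jy
        for jx in range(arr.n_across):
            cols = idx == jx
            m = mask[np.ix_(rows, cols)]
            if m.mean() >= arr.min_fill:
                sx[jy, jx] = gx[np.ix_(rows, cols)][m].mean()
                sy[jy, jx] = gy[np.ix_(rows, cols)][m].mean()
                valid[jy, jx] = True
    return SlopeField(sx, sy, valid, arr)


def reference_frame(grid: PupilGrid, arr: LensletArray) -> SHFrame:
    """Noiseless frame of the flat (zero) wavefront: spots at window centers."""
    return render_sh_frame(Wavefront(grid, np.zeros((grid.n_samples,) * 2)), arr)


def render_sh_frame(
    w: Wavefront,
    arr: LensletArray,
    photons: float = 0.0,
    seed: int | None = None,
) -> SHFrame:
    """Render the Shack–Hartmann camera image for a wavefront.

    Each illuminated subaperture gets a Gaussian spot displaced from the
    window center by focal_px × (mean gradient); spots whose displacement
    would leave the window are flagged invalid and left dark (a distorted /
    vignetted focus).  photons > 0 applies Poisson noise with the given
    expected photon count at the brightest spot; photons = 0 is noiseless.
    """
    if photons < 0:
        raise ValueError("photons must be >= 0")
    grads = mean_gradient_field(w, arr)
    fill = _subap_fill(arr, w.grid)
    win = arr.win_px
    frame = np.zeros((arr.frame_px, arr.frame_px))
    centroids = np.full((arr.n_across, arr.n_across, 2), np.nan)
    reference = np.full_like(centroids, np.nan)
    valid = np.zeros((arr.n_across, arr.n_across), dtype=bool)
    half = (win - 1) / 2.0
    yy, xx = np.mgrid[0:win, 0:win]
    max_shift = win / 2.0 - 2.0 * arr.spot_sigma_px
    for jy in range(arr.n_across):
        for jx in range(arr.n_across):
            if not grads.valid[jy, jx]:
                continue
            dx = arr.focal_px * grads.sx[jy, jx]
            dy = arr.focal_px * grads.sy[jy, jx]
            ref_x = jx * win + half
            ref_y = jy * win + half
            reference[jy, jx] = (ref_x, ref_y)
            if abs(dx) > max_shift or abs(dy) > max_shift:
                continue  # spot leaves its window: invalid, dark
            amp = fill[jy, jx]
            spot = amp * np.exp(
                -((xx - half - dx) ** 2 + (yy - half - dy) ** 2)
                / (2 * arr.spot_sigma_px**2)
            )
            frame[jy * win : (jy + 1) * win, jx * win : (jx + 1) * win] += spot
            centroids[jy, jx] = (ref_x + dx, ref_y + dy)
            valid[jy, jx] = True
    if photons > 0:
        peak = frame.max()
        if peak > 0:
            rng = np.random.default_rng(seed)
            frame = rng.poisson(frame / peak * photons).astype(float)
    return SHFrame(frame, centroids, reference, valid, arr, photons)


def find_centroids(frame: SHFrame, threshold_frac: float = 0.1) -> SHFrame:
    """Measure spot centroids per subaperture window.

    Per window: subtract the window median (background), clip negatives,
    and take the center of mass.  A window is valid iff its background-
    subtracted peak exceeds threshold_frac × the brightest window peak in
    the frame.  A zero-signal frame yields all-invalid, no exception.
    """
    arr = frame.arr
    win = arr.win_px
    half = (win - 1) / 2.0
    yy, xx = np.mgrid[0:win, 0:win]
    peaks = np.zeros((arr.n_across, arr.n_across))
    coms = np.full((arr.n_across, arr.n_across, 2), np.nan)
    for jy in range(arr.n_across):
        for jx in range(arr.n_across):
            wimg = frame.image[jy * win : (jy + 1) * win, jx * win : (jx + 1) * win]
            sub = np.clip(wimg - np.median(wimg), 0, None)
            peaks[jy, jx] = sub.max()
            tot = sub.sum()
            if tot > 0:
                coms[jy, jx, 0] = jx * win + (sub * xx).sum() / tot
                coms[jy, jx, 1] = jy * win + (sub * yy).sum() / tot
    gmax = peaks.max()
    valid = (peaks > threshold_frac * gmax) & np.isfinite(coms[..., 0]) if gmax > 0 else np.zeros(peaks.shape, dtype=bool)
    reference = frame.reference.copy()
    # reference positions exist wherever the geometry defines a window
    missing_ref = ~np.isfinite(reference[..., 0])
    ref_x = (np.arange(arr.n_across) * win + half)[None, :] * np.ones((arr.n_across, 1))
    ref_y = (np.arange(arr.n_across) * win + half)[:, None] * np.ones((1, arr.n_across))
    reference[missing_ref, 0] = ref_x[missing_ref]
    reference[missing_ref, 1] = ref_y[missing_ref]
    return SHFrame(frame.image, coms, reference, valid, arr, frame.photon_scale)


def slopes_from_centroids(
    frame: SHFrame, ref: SHFrame, arr: LensletArray
) -> SlopeField:
    """Slopes (µm per normalized unit) from centroid displacements.

    (sx, sy) = (centroid − reference centroid)/focal_px; a subaperture is
    valid only where both the measurement and the reference carry a spot.
    The global mean slope (tip/tilt) is retained here; stripping it is a
    downstream policy.
    """
    if frame.arr.n_across != arr.n_across or ref.arr.n_across != arr.n_across:
        raise GeometryError("lenslet geometry mismatch between frames")
    valid = frame.valid & ref.valid
    if not ref.valid.any():
        raise GeometryError("reference frame has no valid subapertures")
    d = frame.centroids - ref.centroids
    sx = np.where(valid, d[..., 0] / arr.focal_px, 0.0)
    sy = np.where(valid, d[..., 1] / arr.focal_px, 0.0)
    return SlopeField(sx, sy, valid, arr)
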