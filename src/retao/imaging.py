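"""Two-photon image formation through the eye + DM + ETL optical chain.

Stacks are rendered with a piecewise field-varying PSF: the field of view
is divided into tiles, each tile gets the two-photon effective PSF of its
own effective wavefront (ocular aberration at the tile center, plus ETL
defocus, plus the DM correction surface), the phantom density is convolved
per tile, and tiles are blended with bilinear seam weights.  Guide-star
sensing renders a Shack–Hartmann frame of the area-averaged wavefront seen
from a user-defined scan area, exactly as a scanned two-photon guide star
averages the aberrations over the scanned patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter, zoom as nd_zoom
from scipy.signal import fftconvolve

from .dm import SegmentedDM, dm_to_wavefront
from .psf import OpticalConfig, PSF, excitation_psf, two_photon_psf
from .shwfs import LensletArray, SHFrame, SlopeField, find_centroids, reference_frame, render_sh_frame, slopes_from_centroids
from .synth import ETLState, EyeModel, Phantom, aberration_at_field, apply_etl
from .zernike import PupilGrid, Wavefront

__all__ = [
    "ImagingConfig",
    "ImageStack",
    "DimFrameError",
    "effective_wavefront",
    "render_stack",
    "sense_guide_star",
]


class DimFrameError(RuntimeError):
    """Wavefront sensing attempted on a dark (unlabeled) region."""


@dataclass(frozen=True)
class ImagingConfig:
    """Stack-rendering geometry and budgets.

    The default field of view matches the instrument's 580×580 µm² raster;
    tests and examples shrink it.  ``pupil_samples``/``pad_factor`` set the
    PSF engine resolution used during rendering (coarser than the
    metrology default, which is fine for µm-scale image voxels).
    """

    fov_um: float = 580.0
    px_um: float = 2.0
    z_range_um: tuple[float, float] = (-16.0, 16.0)
    dz_um: float = 4.0
    tiles: int = 5
    photons_per_au: float = 0.0  # 0 = noiseless
    seed: int = 0
    pupil_samples: int = 128
    pad_factor: int = 4
    psf_halfwidth_um: float = 8.0
    psf_halfdepth_um: float = 12.0

    def __post_init__(self) -> None:
        if self.tiles < 1:
            raise ValueError("tiles must be >= 1")
        if self.px_um <= 0:
            raise ValueError("px_um must be positive")


@dataclass
class ImageStack:
    """Rendered two-photon stack with calibrated voxels and provenance."""

    data: np.ndarray  # (z, y, x), nonnegative
    px_um: float
    dz_um: float
    provenance: dict = field(default_factory=dict)

    def mip(self) -> np.ndarray:
        """Maximum-intensity projection along z."""
        return self.data.max(axis=0)


def effective_wavefront(
    eye: EyeModel | None,
    dm: SegmentedDM | None,
    etl: ETLState | None,
    x_um: float,
    y_um: float,
    grid: PupilGrid,
    cfg_opt: OpticalConfig,
) -> Wavefront:
    """Eye aberration at a field point + ETL defocus + DM surface.

    The DM is loaded with the (already negated) corrective wavefront, so a
    good correction cancels the ocular term here.
    """
    w = Wavefront(grid, np.zeros((grid.n_samples,) * 2))
    if eye is not None:
        w = w + aberration_at_field(eye, x_um, y_um, grid)
    if etl is not None:
        w = apply_etl(w, etl)
    if dm is not None and dm.state is not None:
        w = w + dm_to_wavefront(dm, grid)
    return w


def _tile_psf_kernel(w: Wavefront, cfg: ImagingConfig, opt: OpticalConfig) -> np.ndarray:
    """Two-photon PSF resampled to the stack voxel grid (unnormalized).

    Kernels must be scaled by one shared reference (the unaberrated
    kernel's integral) so that aberrated tiles render dimmer, as real
    two-photon signal does; :func:`render_stack` applies that scaling.
    """
    zs = np.arange(-cfg.psf_halfdepth_um, cfg.psf_halfdepth_um + 1e-9, cfg.dz_um)
    opt_r = replace(opt, pad_factor=cfg.pad_factor, z_planes_um=tuple(zs))
    p = two_photon_psf(excitation_psf(w, opt_r))
    dx = p.voxel_um[0]
    # crop laterally to the requested halfwidth, then resample to px_um
    n = p.intensity.shape[-1]
    c = n // 2
    hw = int(round(cfg.psf_halfwidth_um / dx))
    hw = min(hw, c - 1)
    crop = p.intensity[:, c - hw : c + hw + 1, c - hw : c + hw + 1]
    zoomf = dx / cfg.px_um
    # integrate over the output pixel area (box prefilter) before resampling,
    # otherwise the sub-pixel focal peak is aliased away
    box = max(int(round(1.0 / zoomf)), 1)
    if box > 1:
        crop = np.stack([uniform_filter(pl, size=box, mode="constant") for pl in crop])
    out = np.stack([nd_zoom(pl, zoomf, order=1) for pl in crop])
    return np.clip(out, 0, None)


def _resample_phantom(ph: Phantom, cfg: ImagingConfig) -> np.ndarray:
    """Phantom density resampled to the stack voxel grid."""
    dzp, dyp, dxp = ph.voxel_um
    fz = dzp / cfg.dz_um
    fy = dyp / cfg.px_um
    fx = dxp / cfg.px_um
    if np.allclose([fz, fy, fx], 1.0):
        return ph.density.astype(float)
    vol = ph.density.astype(float)
    sizes = tuple(max(int(round(1.0 / f)), 1) for f in (fz, fy, fx))
    if any(s > 1 for s in sizes):  # box prefilter against downsampling aliasing
        vol = uniform_filter(vol, size=sizes, mode="constant")
    return np.clip(nd_zoom(vol, (fz, fy, fx), order=1), 0, None)


def render_stack(
    ph: Phantom,
    eye: EyeModel | None = None,
    dm: SegmentedDM | None = None,
    etl: ETLState | None = None,
    cfg: ImagingConfig | None = None,
    opt: OpticalConfig | None = None,
) -> ImageStack:
    """Render a two-photon stack of a phantom through the optical chain.

    Per field tile the density is convolved with that tile's two-photon
    PSF; tiles are blended with bilinear weights centred on the tile
    centres so the PSF varies smoothly across the field.  Poisson noise is
    applied at cfg.photons_per_au expected photons per arbitrary intensity
    unit (0 = noiseless).
    """
    cfg = cfg or ImagingConfig()
    opt = opt or OpticalConfig()
    grid = PupilGrid(cfg.pupil_samples)
    vol = _resample_phantom(ph, cfg)
    nz, ny, nx = vol.shape
    t = cfg.tiles
    # tile centers in field µm, image coordinates centered on the volume
    ext_x = nx * cfg.px_um
    ext_y = ny * cfg.px_um
    cxs = (np.arange(t) + 0.5) / t * ext_x - ext_x / 2
    cys = (np.arange(t) + 0.5) / t * ext_y - ext_y / 2
    xs_pix = (np.arange(nx) + 0.5) * cfg.px_um - ext_x / 2
    ys_pix = (np.arange(ny) + 0.5) * cfg.px_um - ext_y / 2
    out = np.zeros_like(vol)
    wsum = np.zeros((ny, nx))
    flat = Wavefront(grid, np.zeros((grid.n_samples,) * 2))
    ref_sum = _tile_psf_kernel(flat, cfg, opt).sum()
    for iy, cy in enumerate(cys):
        wy = _blend_weight(ys_pix, cy, ext_y / t)
        for ix, cx in enumerate(cxs):
            w_eff = effective_wavefront(eye, dm, etl, cx, cy, grid, opt)
            kern = _tile_psf_kernel(w_eff, cfg, opt) / ref_sum
            conv = fftconvolve(vol, kern, mode="same")
            wx = _blend_weight(xs_pix, cx, ext_x / t)
            wgt = wy[:, None] * wx[None, :]
            out += conv * wgt[None, :, :]
            wsum += wgt
    out /= np.maximum(wsum, 1e-12)[None, :, :]
    out = np.clip(out, 0, None)
    if cfg.photons_per_au > 0:
        rng = np.random.default_rng(cfg.seed)
        out = rng.poisson(out * cfg.photons_per_au).astype(float)
    prov = {
        "seed": cfg.seed,
        "tiles": t,
        "photons_per_au": cfg.photons_per_au,
        "eye_seed": getattr(eye, "seed", None),
        "etl_current_ma": getattr(etl, "current_ma", None),
        "dm_segments": getattr(dm, "n_segments", None),
    }
    return ImageStack(out, cfg.px_um, cfg.dz_um, prov)


def _blend_weight(coords: np.ndarray, center: float, tile_size: float) -> np.ndarray:
    """Triangular (bilinear) blending weight around a tile center."""
    return np.clip(1.0 - np.abs(coords - center) / tile_size, 0.0, None) + 1e-9


def sense_guide_star(
    ph: Phantom,
    eye: EyeModel | None,
    dm: SegmentedDM | None,
    etl: ETLState | None,
    area_center_um: tuple[float, float] = (0.0, 0.0),
    area_side_um: float = 19.0,
    arr: LensletArray | None = None,
    photons: float = 0.0,
    seed: int = 0,
    grid: PupilGrid | None = None,
    n_points: int = 5,
) -> SlopeField:
    """Measure slopes of the area-averaged wavefront from a scanned guide star.

    The guide star is scanned over a square area (default 19 µm side, the
    instrument's default sensing patch); what the sensor sees is the mean
    of the field-dependent aberration over the scanned points, plus ETL
    and DM terms.  The area must contain fluorescent structure: a dark
    (unlabeled) area raises :class:`DimFrameError`, mirroring failed
    sensing on empty retina.
    """
    arr = arr or LensletArray()
    grid = grid or PupilGrid()
    cx, cy = area_center_um
    _check_area_has_signal(ph, cx, cy, area_side_um)
    offs = (np.arange(n_points) + 0.5) / n_points - 0.5
    ws = []
    for oy in offs:
        for ox in offs:
            ws.append(
                effective_wavefront(
                    eye, dm, etl, cx + ox * area_side_um, cy + oy * area_side_um, grid,
                    OpticalConfig(),
                ).phase
            )
    w_mean = Wavefront(grid, np.mean(ws, axis=0))
    frame = render_sh_frame(w_mean, arr, photons=photons, seed=seed)
    frame = find_centroids(frame)
    ref = find_centroids(reference_frame(grid, arr))
    return slopes_from_centroids(frame, ref, arr)


def _check_area_has_signal(ph: Phantom, cx: float, cy: float, side: float) -> None:
    nz, ny, nx = ph.density.shape
    dy, dx = ph.voxel_um[1], ph.voxel_um[2]
    ext_x, ext_y = nx * dx, ny * dy
    x0 = int(np.clip((cx - side / 2 + ext_x / 2) / dx, 0, nx))
    x1 = int(np.clip((cx + side / 2 + ext_x / 2) / dx, 0, nx))
    y0 = int(np.clip((cy - side / 2 + ext_y / 2) / dy, 0, ny))
    y1 = int(np.clip((cy + side / 2 + ext_y / 2) / dy, 0, ny))
    patch = ph.density[:, y0:y1, x0:x1]
    if patch.size == 0 or patch.sum() <= 0:
        raise DimFrameError(
            f"no fluorescent structure in the {side:g} µm sensing area at ({cx:g}, {cy:g})"
        )
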