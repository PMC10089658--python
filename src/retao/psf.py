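"""Scalar Fourier-optics excitation PSF and two-photon effective PSF.

The excitation point-spread function is |FFT{P(ρ) exp(i 2π W/λ + i φ_z)}|²
with the pupil P the unit disk, W the aberration map in µm, and the defocus
phase φ_z using the high-NA spherical-cap convention
φ_z = (2π/λ) z √(n² − NA² ρ²).  The two-photon effective PSF is the
pointwise square of the excitation intensity; it sets both resolution and
signal in two-photon fluorescence microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .zernike import PupilGrid, Wavefront

__all__ = [
    "OpticalConfig",
    "PSF",
    "SamplingError",
    "NoPeakError",
    "excitation_psf",
    "two_photon_psf",
    "on_axis_intensity",
    "strehl",
    "fwhm",
]


class SamplingError(ValueError):
    """Pupil sampling insufficient for the requested propagation."""


class NoPeakError(ValueError):
    """Profile has no interior peak to measure."""


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-side optical parameters.

    Defaults describe the mouse-eye imaging path: NA 0.49 through the eye's
    own optics, 920 nm two-photon excitation, vitreous index 1.33.
    """

    na: float = 0.49
    wavelength_um: float = 0.92
    n_immersion: float = 1.33
    pad_factor: int = 8
    z_planes_um: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if not 0 < self.na < self.n_immersion:
            raise ValueError(f"need 0 < NA < n_immersion, got NA={self.na}")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.pad_factor < 4:
            raise SamplingError(f"pad_factor must be >= 4, got {self.pad_factor}")

    @property
    def lateral_spacing_um(self) -> float:
        """Image-plane sample spacing: λ / (2 NA pad_factor)."""
        return self.wavelength_um / (2 * self.na * self.pad_factor)


@dataclass
class PSF:
    """3D intensity distribution with calibrated voxel size (dx, dy, dz µm).

    Axis order is (z, y, x).  ``dz_um`` is meaningful only for uniformly
    spaced z_planes; arbitrary plane lists keep the plane positions.
    """

    intensity: np.ndarray
    voxel_um: tuple[float, float, float]
    z_planes_um: tuple[float, ...]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("PSF intensity must be 3D (z, y, x)")
        if np.any(self.intensity < 0):
            raise ValueError("PSF intensity must be nonnegative")

    @property
    def peak(self) -> float:
        return float(self.intensity.max())

    def lateral_profile(self) -> tuple[np.ndarray, float]:
        """In-focus x-profile through the brightest voxel and its spacing."""
        iz, iy, ix = np.unravel_index(int(self.intensity.argmax()), self.intensity.shape)
        return self.intensity[iz, iy, :], self.voxel_um[0]

    def axial_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Peak intensity per z-plane and the plane positions (µm)."""
        prof = self.intensity.max(axis=(1, 2))
        return prof, np.asarray(self.z_planes_um)


def _defocus_opd(grid: PupilGrid, cfg: OpticalConfig) -> np.ndarray:
    """Optical path in µm per µm of axial shift: √(n² − NA² ρ²)."""
    x, y = grid.coords
    rho2 = x * x + y * y
    return np.sqrt(np.maximum(cfg.n_immersion**2 - cfg.na**2 * rho2, 0.0))


def _pupil_field(w: Wavefront, cfg: OpticalConfig, z_um: float) -> np.ndarray:
    mask = w.grid.mask
    opd = w.phase + z_um * _defocus_opd(w.grid, cfg)
    field = np.zeros(mask.shape, dtype=complex)
    field[mask] = np.exp(1j * 2 * np.pi * opd[mask] / cfg.wavelength_um)
    return field


def excitation_psf(w: Wavefront, cfg: OpticalConfig | None = None) -> PSF:
    """Scalar-diffraction excitation intensity of the aberrated focus.

    Normalized so the unaberrated on-axis peak equals 1.  One FFT per
    requested z plane; lateral spacing is λ/(2·NA·pad_factor).
    """
    cfg = cfg or OpticalConfig()
    n = w.grid.n_samples
    npad = n * cfg.pad_factor
    # Nyquist: aberration phase step between adjacent pupil samples must
    # stay below π for the padded FFT to sample the focal field faithfully.
    mask = w.grid.mask
    step = np.nanmax(np.abs(np.diff(np.where(mask, w.phase, np.nan), axis=-1)))
    if np.isfinite(step) and step * 2 * np.pi / cfg.wavelength_um > np.pi:
        raise SamplingError(
            "pupil phase gradient too steep for this grid/pad_factor"
        )
    norm = float(mask.sum()) ** 2
    planes = []
    for z in cfg.z_planes_um:
        field = _pupil_field(w, cfg, z)
        # padding the un-centered field only adds a linear phase (pure image
        # translation); intensity is unaffected, so no pre-shift is needed
        amp = np.fft.fftshift(np.fft.fft2(field, s=(npad, npad)))
        planes.append(np.abs(amp) ** 2 / norm)
    dx = cfg.lateral_spacing_um
    zs = np.asarray(cfg.z_planes_um, dtype=float)
    dz = float(zs[1] - zs[0]) if len(zs) > 1 else 0.0
    return PSF(np.stack(planes), (dx, dx, dz), tuple(zs))


def on_axis_intensity(w: Wavefront, cfg: OpticalConfig, z_um: np.ndarray) -> np.ndarray:
    """Excitation intensity on the optical axis for each z, unit unaberrated peak.

    The on-axis focal field is the plain sum of the pupil phasor, so no FFT
    is needed; this is the fast path for axial-profile measurements.
    """
    mask = w.grid.mask
    opd0 = w.phase[mask]
    dz_opd = _defocus_opd(w.grid, cfg)[mask]
    k = 2 * np.pi / cfg.wavelength_um
    z_um = np.atleast_1d(np.asarray(z_um, dtype=float))
    out = np.empty(len(z_um))
    for i, z in enumerate(z_um):
        out[i] = np.abs(np.exp(1j * k * (opd0 + z * dz_opd)).sum()) ** 2
    return out / mask.sum() ** 2


def two_photon_psf(p: PSF) -> PSF:
    """Two-photon effective PSF: pointwise square of the excitation intensity.

    With the excitation normalized to unit unaberrated peak, the squared
    distribution keeps that normalization; its FWHM is strictly narrower
    than the excitation's in every direction.
    """
    return PSF(p.intensity**2, p.voxel_um, p.z_planes_um)


def strehl(w: Wavefront, cfg: OpticalConfig | None = None) -> float:
    """Peak of the aberrated excitation PSF over the unaberrated peak.

    Searched over the configured z planes; piston does not affect it.
    """
    cfg = cfg or OpticalConfig()
    p = excitation_psf(w, cfg)
    return float(p.intensity.max())


def fwhm(profile: np.ndarray, spacing_um: float) -> float:
    """Full width at half maximum of a sampled 1D profile, in µm.

    Half level is baseline + (max − baseline)/2 with baseline = profile
    minimum; crossings on either side of the peak are located by linear
    interpolation.  Raises :class:`NoPeakError` for flat or monotone
    profiles (peak on the boundary).
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise NoPeakError("profile must be 1D with at least 3 samples")
    if np.any(p < 0):
        raise ValueError("profile must be nonnegative")
    imax = int(p.argmax())
    baseline = float(p.min())
    height = float(p[imax]) - baseline
    if height <= 0 or imax == 0 or imax == len(p) - 1:
        raise NoPeakError("profile has no interior peak")
    half = baseline + height / 2.0

    def _cross(idx_range) -> float:
        prev = imax
        for i in idx_range:
            if p[i] <= half:
                # linear interpolation between i and prev
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + frac * (i - prev)
            prev = i
        raise NoPeakError("profile does not fall to half maximum")

    left = _cross(range(imax - 1, -1, -1))
    right = _cross(range(imax + 1, len(p)))
    return float((right - left) * spacing_um)
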