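"""Zernike basis, pupil grids, and wavefront arithmetic.

All other modules express aberrations in this module's currency: a
:class:`Wavefront` is an optical-path-difference map in micrometres over a
unit pupil, and a :class:`ZernikeCoeffs` is its modal view in the Noll
convention (j = 1 piston, 2-3 tip/tilt, 4 defocus) with unit-rms
normalization, so a coefficient of ``c`` µm means that mode alone has
``c`` µm rms over the pupil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "PupilGrid",
    "Wavefront",
    "ZernikeCoeffs",
    "GeometryError",
    "noll_to_nm",
    "zernike_mode",
    "basis_matrix",
    "compose",
    "decompose",
    "remove_modes",
    "rms",
    "pv",
]


class GeometryError(ValueError):
    """Incompatible or degenerate pupil geometry."""


@dataclass(frozen=True)
class PupilGrid:
    """Square sampling grid over the unit pupil.

    Parameters
    ----------
    n_samples : int
        Samples per side; the pupil diameter spans the full grid.
    pupil_radius_mm : float
        Physical pupil radius, informational only (all geometry is in
        normalized coordinates).
    """

    n_samples: int = 256
    pupil_radius_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 32:
            raise GeometryError(f"n_samples must be >= 32, got {self.n_samples}")

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized (x, y) coordinate arrays, each n_samples x n_samples."""
        c = np.linspace(-1.0, 1.0, self.n_samples)
        return np.meshgrid(c, c, indexing="xy")

    @property
    def mask(self) -> np.ndarray:
        x, y = self.coords
        return x * x + y * y <= 1.0

    @property
    def sample_spacing(self) -> float:
        return 2.0 / (self.n_samples - 1)


@dataclass
class Wavefront:
    """Optical path map in µm sampled on a :class:`PupilGrid`.

    ``phase`` is defined over the full square array (values outside the
    pupil mask are kept so that finite-difference gradients are clean up
    to the rim); statistics (`rms`, `pv`) only ever look inside the mask.
    """

    grid: PupilGrid
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        n = self.grid.n_samples
        if self.phase.shape != (n, n):
            raise GeometryError(
                f"phase shape {self.phase.shape} does not match grid ({n}, {n})"
            )

    def __add__(self, other: "Wavefront") -> "Wavefront":
        _check_same_grid(self, other)
        return Wavefront(self.grid, self.phase + other.phase)

    def __sub__(self, other: "Wavefront") -> "Wavefront":
        _check_same_grid(self, other)
        return Wavefront(self.grid, self.phase - other.phase)

    def __mul__(self, scalar: float) -> "Wavefront":
        return Wavefront(self.grid, self.phase * float(scalar))

    __rmul__ = __mul__

    def __neg__(self) -> "Wavefront":
        return Wavefront(self.grid, -self.phase)

    def rms(self) -> float:
        return rms(self)

    def pv(self) -> float:
        return pv(self)


@dataclass
class ZernikeCoeffs:
    """Noll-ordered, unit-rms-normalized Zernike amplitudes in µm rms.

    ``coeffs[0]`` is Noll j = 1 (piston).
    """

    coeffs: np.ndarray
    ordering: str = "noll"

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))

    def __getitem__(self, j: int) -> float:
        """Amplitude of Noll mode j (1-based)."""
        return float(self.coeffs[j - 1])

    @property
    def n_modes(self) -> int:
        return len(self.coeffs)


def _check_same_grid(a: Wavefront, b: Wavefront) -> None:
    if a.grid.n_samples != b.grid.n_samples:
        raise GeometryError(
            f"grid mismatch: {a.grid.n_samples} vs {b.grid.n_samples} samples"
        )


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index j >= 1 to radial order n and azimuthal frequency m.

    Negative m denotes the sine mode, positive the cosine mode.
    """
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def _zernike_values(j: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, m = noll_to_nm(j)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    r = _radial_poly(n, m, rho)
    if m == 0:
        norm = math.sqrt(n + 1)
        ang = 1.0
    else:
        norm = math.sqrt(2 * (n + 1))
        ang = np.cos(m * theta) if m > 0 else np.sin(-m * theta)
    return norm * r * ang


def zernike_mode(grid: PupilGrid, j: int) -> Wavefront:
    """Unit-rms Noll mode j sampled on the grid (full square; mask applies
    only to statistics).

    The piston mode (j = 1) is the constant 1; its "rms" under the unit-rms
    convention is its value, not the piston-removed rms.
    """
    if j < 1:
        raise IndexError(f"Zernike mode index must be >= 1, got {j}")
    x, y = grid.coords
    return Wavefront(grid, _zernike_values(j, x, y))


@lru_cache(maxsize=8)
def _basis_cache(n_samples: int, n_modes: int) -> np.ndarray:
    grid = PupilGrid(n_samples)
    x, y = grid.coords
    return np.stack(
        [_zernike_values(j, x, y) for j in range(1, n_modes + 1)], axis=0
    )


def basis_matrix(grid: PupilGrid, n_modes: int) -> np.ndarray:
    """(n_modes, n, n) array of the first n_modes Noll modes on the grid."""
    return _basis_cache(grid.n_samples, n_modes)


def compose(coeffs: ZernikeCoeffs, grid: PupilGrid) -> Wavefront:
    """Wavefront = sum_j coeffs[j] * Z_j on the grid."""
    b = basis_matrix(grid, coeffs.n_modes)
    return Wavefront(grid, np.tensordot(coeffs.coeffs, b, axes=1))


def decompose(w: Wavefront, n_modes: int) -> ZernikeCoeffs:
    """Least-squares projection of w onto the first n_modes Noll modes.

    Exact (to machine precision) when w lies in the span of the fitted
    modes; otherwise the in-mask least-squares fit.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    mask = w.grid.mask
    b = basis_matrix(w.grid, n_modes)
    a = b[:, mask].T  # (n_pix, n_modes)
    sol, *_ = np.linalg.lstsq(a, w.phase[mask], rcond=None)
    return ZernikeCoeffs(sol)


def remove_modes(w: Wavefront, modes: set[int] | list[int] | tuple[int, ...]) -> Wavefront:
    """Subtract the least-squares projection of w onto the listed Noll modes.

    Idempotent; the result is orthogonal (over the mask) to each removed
    mode.
    """
    modes = sorted(set(int(j) for j in modes))
    if not modes:
        return Wavefront(w.grid, w.phase.copy())
    mask = w.grid.mask
    b = basis_matrix(w.grid, max(modes))
    sel = np.array(modes) - 1
    a = b[sel][:, mask].T  # project onto the span of the listed modes only
    sol, *_ = np.linalg.lstsq(a, w.phase[mask], rcond=None)
    removal = np.zeros(max(modes))
    removal[sel] = sol
    return w - compose(ZernikeCoeffs(removal), w.grid)


def rms(w: Wavefront) -> float:
    """Piston-free rms of the phase over the pupil mask, in µm."""
    mask = w.grid.mask
    if not mask.any():
        raise GeometryError("empty pupil mask")
    vals = w.phase[mask]
    return float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))


def pv(w: Wavefront) -> float:
    """Peak-to-valley of the phase over the pupil mask, in µm."""
    mask = w.grid.mask
    if not mask.any():
        raise GeometryError("empty pupil mask")
    vals = w.phase[mask]
    return float(vals.max() - vals.min())
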