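"""Wavefront reconstruction from Shack–Hartmann slope fields.

Two standard estimators are provided: zonal least squares on the Southwell
geometry (phase nodes co-located with the slope samples, adjacent nodes
coupled through the average of their slopes) and modal least squares
against the subaperture-averaged gradients of the Zernike basis.  Both
return piston-free wavefronts; the corrective wavefront for a deformable
mirror is the negated reconstruction with tip and tilt stripped (they
redirect the beam rather than blur the focus).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator

from .shwfs import LensletArray, SlopeField, mean_gradient_field
from .zernike import (
    PupilGrid,
    Wavefront,
    ZernikeCoeffs,
    compose,
    zernike_mode,
)

__all__ = [
    "ReconstructionResult",
    "ReconstructionError",
    "ConditioningError",
    "reconstruct_zonal",
    "reconstruct_modal",
    "corrective_from_measurement",
]


class ReconstructionError(RuntimeError):
    """No reconstructable slope data."""


class ConditioningError(RuntimeError):
    """Modal system too ill-conditioned for the requested mode count."""


@dataclass
class ReconstructionResult:
    wavefront: Wavefront
    coeffs: ZernikeCoeffs | None
    residual_slope_rms: float
    method: str
    n_components: int = 1


@lru_cache(maxsize=8)
def _modal_gradient_matrix(
    n_samples: int, n_across: int, n_modes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subaperture mean (gx, gy) of each Zernike mode, plus validity.

    Built with the same subaperture-averaging operator as the measurement
    model, so modal inversion is consistent with the forward render.
    """
    grid = PupilGrid(n_samples)
    arr = LensletArray(n_across=n_across)
    gx_list, gy_list = [], []
    valid = None
    for j in range(1, n_modes + 1):
        sf = mean_gradient_field(zernike_mode(grid, j), arr)
        gx_list.append(sf.sx)
        gy_list.append(sf.sy)
        valid = sf.valid
    return np.stack(gx_list), np.stack(gy_list), valid  # type: ignore[return-value]


def reconstruct_modal(
    slopes: SlopeField, n_modes: int = 25, grid: PupilGrid | None = None
) -> ReconstructionResult:
    """Least-squares Zernike fit to a slope field.

    Fits modes 2..n_modes (piston has no gradient and is fixed at 0);
    returns the coefficient vector and the composed, piston-free wavefront.
    """
    grid = grid or PupilGrid()
    v = slopes.valid
    n_meas = int(v.sum())
    if n_modes > n_meas * 2:
        raise ConditioningError(
            f"{n_modes} modes from {n_meas} valid subapertures ({2 * n_meas} slopes)"
        )
    gx, gy, basis_valid = _modal_gradient_matrix(
        grid.n_samples, slopes.arr.n_across, n_modes
    )
    vv = v & basis_valid
    # design matrix: columns are modes 2..n_modes (piston dropped)
    a = np.concatenate([gx[1:, vv].T, gy[1:, vv].T], axis=0)
    b = np.concatenate([slopes.sx[vv], slopes.sy[vv]])
    cond = np.linalg.cond(a)
    if cond > 1e8:
        raise ConditioningError(f"modal system condition number {cond:.3g}")
    sol, res, *_ = np.linalg.lstsq(a, b, rcond=None)
    coeffs = ZernikeCoeffs(np.concatenate([[0.0], sol]))
    resid = a @ sol - b
    resid_rms = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
    w = compose(coeffs, grid)
    w = Wavefront(grid, w.phase - w.phase[grid.mask].mean())
    return ReconstructionResult(w, coeffs, resid_rms, "modal")


def _second_diff(s: np.ndarray, v: np.ndarray, axis: int) -> np.ndarray:
    """Second difference of a slope field along an axis, one-sided at the rim."""
    out = np.zeros_like(s)
    done = np.zeros(s.shape, dtype=bool)
    sh = np.roll(s, -1, axis=axis)
    sl = np.roll(s, 1, axis=axis)
    vh = np.roll(v, -1, axis=axis)
    vl = np.roll(v, 1, axis=axis)
    both = v & vh & vl
    out[both] = (sh - 2 * s + sl)[both]
    done |= both
    # one-sided: shift the stencil inward by one node
    sh2 = np.roll(s, -2, axis=axis)
    vh2 = np.roll(v, -2, axis=axis)
    fwd = v & vh & vh2 & ~done
    out[fwd] = (sh2 - 2 * sh + s)[fwd]
    done |= fwd
    sl2 = np.roll(s, 2, axis=axis)
    vl2 = np.roll(v, 2, axis=axis)
    bwd = v & vl & vl2 & ~done
    out[bwd] = (s - 2 * sl + sl2)[bwd]
    return out


def _cell_mean_to_point(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Convert subaperture-mean slopes to point slopes at cell centers.

    A cell average differs from the center value by (h²/24)(s_xx + s_yy);
    the Laplacian is estimated from neighboring slopes, shifting the
    stencil inward at the pupil rim.
    """
    out = s.copy()
    corr = _second_diff(s, v, 0) + _second_diff(s, v, 1)
    out[v] -= corr[v] / 24.0
    return out


def _third_diff_for_link(s: np.ndarray, v: np.ndarray, jy: int, jx: int, axis: str, n: int) -> float:
    """Third-difference estimate for the link (jy,jx)→next along an axis.

    Tries the quadruple centered on the link first, then the two shifted
    quadruples (one-sided at the pupil rim); returns 0 when no complete
    stencil exists.
    """

    def get(dj: int):
        if axis == "x":
            j2 = jx + dj
            if 0 <= j2 < n and v[jy, j2]:
                return s[jy, j2]
        else:
            j2 = jy + dj
            if 0 <= j2 < n and v[j2, jx]:
                return s[j2, jx]
        return None

    for a in (-1, -2, 0):
        q = [get(a), get(a + 1), get(a + 2), get(a + 3)]
        if all(x is not None for x in q):
            return q[3] - q[2] - q[1] + q[0]
    return 0.0


def _southwell_system(slopes: SlopeField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows of the Southwell finite-difference system over valid nodes.

    Links use the trapezoid rule with a third-difference correction
    (error O(h⁵) instead of O(h³)); the correction stencil shifts inward
    at the pupil rim.
    """
    v = slopes.valid
    n = slopes.arr.n_across
    h = 2.0 / n  # node spacing in normalized pupil units
    sx, sy = slopes.sx, slopes.sy
    node_id = -np.ones((n, n), dtype=int)
    node_id[v] = np.arange(v.sum())
    rows, rhs = [], []
    for jy in range(n):
        for jx in range(n):
            if not v[jy, jx]:
                continue
            if jx + 1 < n and v[jy, jx + 1]:
                r = np.zeros(v.sum())
                r[node_id[jy, jx + 1]] = 1.0
                r[node_id[jy, jx]] = -1.0
                val = h * 0.5 * (sx[jy, jx] + sx[jy, jx + 1])
                val -= (h / 24.0) * _third_diff_for_link(sx, v, jy, jx, "x", n)
                rows.append(r)
                rhs.append(val)
            if jy + 1 < n and v[jy + 1, jx]:
                r = np.zeros(v.sum())
                r[node_id[jy + 1, jx]] = 1.0
                r[node_id[jy, jx]] = -1.0
                val = h * 0.5 * (sy[jy, jx] + sy[jy + 1, jx])
                val -= (h / 24.0) * _third_diff_for_link(sy, v, jy, jx, "y", n)
                rows.append(r)
                rhs.append(val)
    return np.array(rows), np.array(rhs), node_id


def _connected_components(valid: np.ndarray) -> np.ndarray:
    from scipy.ndimage import label

    lab, _ = label(valid)
    return lab


def reconstruct_zonal(
    slopes: SlopeField,
    grid: PupilGrid | None = None,
    slopes_are_cell_means: bool = True,
) -> ReconstructionResult:
    """Zonal least-squares reconstruction on the Southwell geometry.

    Solves the finite-difference system on the largest connected component
    of valid subapertures (others are dropped and counted), pins piston to
    zero mean, and resamples node values to the pupil grid: smooth
    (Clough–Tocher) interpolation inside the node hull, first-order
    extension (nearest node value + its slopes × offset) out to the pupil
    rim.  With ``slopes_are_cell_means`` (the physical Shack–Hartmann
    case) the subaperture-mean slopes are first converted to center point
    slopes; pass False when feeding point-sampled gradients.
    """
    grid = grid or PupilGrid()
    v = slopes.valid.copy()
    if v.sum() < 3:
        raise ReconstructionError("need at least 3 valid subapertures")
    lab = _connected_components(v)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = sizes.argmax()
    n_components = int((sizes > 0).sum())
    vv_keep = lab == keep
    sx, sy = slopes.sx, slopes.sy
    if slopes_are_cell_means:
        sx = _cell_mean_to_point(sx, vv_keep)
        sy = _cell_mean_to_point(sy, vv_keep)
    comp = SlopeField(sx, sy, vv_keep, slopes.arr)
    a, b, node_id = _southwell_system(comp)
    if len(a) == 0:
        raise ReconstructionError("valid subapertures are not connected")
    # pin piston: zero-mean constraint row
    a = np.vstack([a, np.ones((1, a.shape[1]))])
    b = np.concatenate([b, [0.0]])
    phi, *_ = np.linalg.lstsq(a, b, rcond=None)
    resid = a[:-1] @ phi - b[:-1]
    resid_rms = float(np.sqrt(np.mean(resid**2)))

    phase = _resample_nodes(comp, phi, node_id, grid)
    phase -= phase[grid.mask].mean()
    w = Wavefront(grid, phase)
    return ReconstructionResult(w, None, resid_rms, "zonal", n_components)


def _first_diff(s: np.ndarray, v: np.ndarray, h: float, axis: int) -> np.ndarray:
    """First difference of a node field, centered where possible, one-sided at the rim."""
    out = np.zeros_like(s)
    done = np.zeros(s.shape, dtype=bool)
    sh, sl = np.roll(s, -1, axis=axis), np.roll(s, 1, axis=axis)
    vh, vl = np.roll(v, -1, axis=axis), np.roll(v, 1, axis=axis)
    both = v & vh & vl
    out[both] = ((sh - sl) / (2 * h))[both]
    done |= both
    fwd = v & vh & ~done
    out[fwd] = ((sh - s) / h)[fwd]
    done |= fwd
    bwd = v & vl & ~done
    out[bwd] = ((s - sl) / h)[bwd]
    return out


def _resample_nodes(
    comp: SlopeField, phi: np.ndarray, node_id: np.ndarray, grid: PupilGrid
) -> np.ndarray:
    """Node values → pupil-grid map by bicubic Hermite patches.

    Each lattice cell whose four corners are valid nodes gets the bicubic
    Hermite surface defined by the corner phases, the measured corner
    slopes, and finite-difference cross derivatives; rim samples evaluate
    the nearest complete cell's patch (mild polynomial extrapolation over
    at most about one node spacing).  Falls back to blended first-order
    node patches when no complete cell exists.
    """
    from scipy.spatial import cKDTree

    n = comp.arr.n_across
    h = 2.0 / n
    v = comp.valid
    sx, sy = comp.sx, comp.sy
    cxs, cys = comp.arr.subap_centers()
    x, y = grid.coords
    q = np.stack([x.ravel(), y.ravel()], axis=1)
    node_phase = np.full((n, n), np.nan)
    node_phase[v] = phi[node_id[v]]

    cell_ok = v[:-1, :-1] & v[:-1, 1:] & v[1:, :-1] & v[1:, 1:]
    if not cell_ok.any():
        pts = np.stack([cxs[v], cys[v]], axis=1)
        vals = phi[node_id[v]]
        tree = cKDTree(pts)
        k = min(3, len(pts))
        dist, idx = tree.query(q, k=k)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        dxq = q[:, None, 0] - pts[idx, 0]
        dyq = q[:, None, 1] - pts[idx, 1]
        patch = vals[idx] + sx[v][idx] * dxq + sy[v][idx] * dyq
        wgt = 1.0 / (dist**2 + (0.05 * h) ** 2)
        return ((patch * wgt).sum(axis=1) / wgt.sum(axis=1)).reshape(x.shape)

    sxy = 0.5 * (_first_diff(sx, v, h, 0) + _first_diff(sy, v, h, 1))
    ok_idx = np.argwhere(cell_ok)  # (jy, jx) of each cell's lower corner
    cell_centers = np.stack(
        [cxs[0][ok_idx[:, 1]] + h / 2, cys[:, 0][ok_idx[:, 0]] + h / 2], axis=1
    )
    tree = cKDTree(cell_centers)
    _, nearest = tree.query(q)
    cj = ok_idx[nearest]
    x0 = cxs[0][cj[:, 1]]
    y0 = cys[:, 0][cj[:, 0]]
    t = (q[:, 0] - x0) / h
    u = (q[:, 1] - y0) / h

    def hermite(s):
        return (
            2 * s**3 - 3 * s**2 + 1,
            s**3 - 2 * s**2 + s,
            -2 * s**3 + 3 * s**2,
            s**3 - s**2,
        )

    h00, h10, h01, h11 = hermite(t)
    g00, g10, g01, g11 = hermite(u)
    val = np.zeros(len(q))
    for dy_ in (0, 1):
        for dx_ in (0, 1):
            f = node_phase[cj[:, 0] + dy_, cj[:, 1] + dx_]
            fx = sx[cj[:, 0] + dy_, cj[:, 1] + dx_] * h
            fy = sy[cj[:, 0] + dy_, cj[:, 1] + dx_] * h
            fxy = sxy[cj[:, 0] + dy_, cj[:, 1] + dx_] * h * h
            hx = (h00, h10) if dx_ == 0 else (h01, h11)
            gy = (g00, g10) if dy_ == 0 else (g01, g11)
            val += f * hx[0] * gy[0] + fx * hx[1] * gy[0] + fy * hx[0] * gy[1] + fxy * hx[1] * gy[1]
    return val.reshape(x.shape)


def corrective_from_measurement(
    rec: ReconstructionResult, strip_defocus: bool = False
) -> Wavefront:
    """Corrective wavefront: the negated reconstruction, tip/tilt removed.

    Tip and tilt steer the focus rather than blur it, so they are stripped
    from corrections by convention; measured defocus is kept by default
    (set strip_defocus to leave focus control to the tunable lens).
    """
    from .zernike import remove_modes

    modes = {1, 2, 3}
    if strip_defocus:
        modes.add(4)
    return remove_modes(-1.0 * rec.wavefront, modes)
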