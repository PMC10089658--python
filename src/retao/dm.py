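"""Segmented deformable mirror: hexagonal piston/tip/tilt segment layout
and least-squares fitting of corrective wavefronts.

The modeled device has 163 independent segments, each controlling piston
(height), tip and tilt; the default geometry is a 7-ring hexagonal tiling
(169 segments) with the six outermost corner segments removed.  Segments
are independent: no inter-segment continuity is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .zernike import GeometryError, PupilGrid, Wavefront

__all__ = ["SegmentedDM", "StateError", "build_hex_layout", "dm_to_wavefront", "fit_dm"]


class StateError(RuntimeError):
    """DM state missing or not initialized."""


@dataclass
class SegmentedDM:
    """Hexagonal-segment mirror state in normalized pupil coordinates.

    state[k] = (piston µm, tipx µm/unit, tilty µm/unit): within segment k the
    surface is piston + tipx·(x − cx) + tilty·(y − cy).
    """

    centers: np.ndarray  # (n_seg, 2)
    pitch: float
    state: np.ndarray | None = None  # (n_seg, 3)
    flagged: np.ndarray | None = None  # segments set from neighbors, not fit

    @property
    def n_segments(self) -> int:
        return len(self.centers)

    def zeroed(self) -> "SegmentedDM":
        dm = SegmentedDM(self.centers, self.pitch)
        dm.state = np.zeros((self.n_segments, 3))
        return dm

    def segment_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Owning segment per sample: nearest center (Voronoi = hex tiling)."""
        pts = np.stack([x.ravel(), y.ravel()], axis=1)
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1).reshape(x.shape)

    def to_table(self):
        """DM state as a pandas DataFrame (segment_id, cx, cy, piston, tipx, tilty)."""
        import pandas as pd

        st = self.state if self.state is not None else np.zeros((self.n_segments, 3))
        return pd.DataFrame(
            {
                "segment_id": np.arange(self.n_segments),
                "cx": self.centers[:, 0],
                "cy": self.centers[:, 1],
                "piston": st[:, 0],
                "tipx": st[:, 1],
                "tilty": st[:, 2],
            }
        )

    @classmethod
    def from_table(cls, df, pitch: float | None = None) -> "SegmentedDM":
        centers = np.stack([df["cx"].to_numpy(), df["cy"].to_numpy()], axis=1)
        if pitch is None:
            d2 = ((centers[:, None] - centers[None, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            pitch = float(np.sqrt(d2.min()))
        dm = cls(centers, pitch)
        dm.state = np.stack(
            [df["piston"].to_numpy(), df["tipx"].to_numpy(), df["tilty"].to_numpy()],
            axis=1,
        ).astype(float)
        return dm


def build_hex_layout(rings: int = 7, drop_corners: bool = True) -> SegmentedDM:
    """Centered hexagonal tiling with `rings` rings around a central segment.

    With drop_corners the six outermost corner segments (the lattice
    vertices of the last ring) are removed; the default (7, True) gives the
    device's 163 segments.  Pitch is set so the segment row along x spans
    the pupil diameter.
    """
    if rings < 1:
        raise ValueError("rings must be >= 1")
    pitch = 1.0 / rings
    u = np.array([pitch, 0.0])
    v = np.array([pitch / 2.0, pitch * np.sqrt(3) / 2.0])
    centers = []
    for a in range(-rings, rings + 1):
        for b in range(-rings, rings + 1):
            ring = max(abs(a), abs(b), abs(a + b))
            if ring > rings:
                continue
            if drop_corners and ring == rings and _is_corner(a, b, rings):
                continue
            centers.append(a * u + b * v)
    dm = SegmentedDM(np.array(centers), pitch)
    dm.state = np.zeros((dm.n_segments, 3))
    return dm


def _is_corner(a: int, b: int, rings: int) -> bool:
    """Corner lattice points of a hex ring: the six at the ring's vertices."""
    return (a, b) in {
        (rings, 0),
        (0, rings),
        (-rings, rings),
        (-rings, 0),
        (0, -rings),
        (rings, -rings),
    }


def dm_to_wavefront(dm: SegmentedDM, grid: PupilGrid) -> Wavefront:
    """Piecewise-planar phase map of the DM surface on the grid.

    Every sample (inside the mask or not) takes the plane of its nearest
    segment, so gradients are defined up to the pupil rim.
    """
    if dm.state is None:
        raise StateError("DM state not initialized; call zeroed() or fit_dm first")
    x, y = grid.coords
    seg = dm.segment_of(x, y)
    p = dm.state[seg]
    cx = dm.centers[seg, 0]
    cy = dm.centers[seg, 1]
    phase = p[..., 0] + p[..., 1] * (x - cx) + p[..., 2] * (y - cy)
    return Wavefront(grid, phase)


def fit_dm(target: Wavefront, dm: SegmentedDM) -> SegmentedDM:
    """Independent least-squares plane fit of each segment to the target.

    A segment with fewer than 3 in-mask samples (or a degenerate sample
    set) is flagged and assigned the mean plane of its neighbors.  Fitting
    a surface the DM itself produced reproduces the state exactly, and the
    operator is linear in the target.
    """
    grid = target.grid
    x, y = grid.coords
    mask = grid.mask
    seg = dm.segment_of(x, y)
    n_seg = dm.n_segments
    state = np.zeros((n_seg, 3))
    flagged = np.zeros(n_seg, dtype=bool)
    for k in range(n_seg):
        sel = (seg == k) & mask
        npix = int(sel.sum())
        if npix < 3:
            flagged[k] = True
            continue
        dx = x[sel] - dm.centers[k, 0]
        dy = y[sel] - dm.centers[k, 1]
        a = np.stack([np.ones(npix), dx, dy], axis=1)
        if np.linalg.matrix_rank(a) < 3:
            flagged[k] = True
            continue
        sol, *_ = np.linalg.lstsq(a, target.phase[sel], rcond=None)
        state[k] = sol
    if flagged.any():
        good = ~flagged
        for k in np.where(flagged)[0]:
            d = np.hypot(*(dm.centers[good] - dm.centers[k]).T)
            nb = np.where(good)[0][d <= 1.5 * dm.pitch]
            if len(nb) == 0:
                nb = np.where(good)[0]
            # neighbor planes evaluated as local planes about this center
            off = dm.centers[nb] - dm.centers[k]
            piston_here = (
                state[nb, 0] - state[nb, 1] * off[:, 0] - state[nb, 2] * off[:, 1]
            )
            state[k, 0] = piston_here.mean()
            state[k, 1:] = state[nb, 1:].mean(axis=0)
    out = SegmentedDM(dm.centers, dm.pitch)
    out.state = state
    out.flagged = flagged
    return out
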