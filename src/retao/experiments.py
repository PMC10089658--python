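"""Canned end-to-end experiments on synthetic eyes.

The sensing-area trade-off experiment reproduces the instrument's central
design question: a small sensing area measures the local aberration
exactly (highest gain at the sensing site, but the correction degrades
away from it on a field-varying eye), while a large area averages out the
local variation (lower peak gain, but image improvement over a wider
field).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dm import build_hex_layout, fit_dm
from .imaging import ImagingConfig, render_stack, sense_guide_star
from .metrics import radial_profile, ratio_map
from .reconstruct import corrective_from_measurement, reconstruct_modal
from .shwfs import LensletArray
from .synth import VesselConfig, make_vessel_phantom, sample_ocular_aberration
from .zernike import PupilGrid

__all__ = ["sensing_area_tradeoff"]


def _brightest_central_spot(ph, search_radius_um: float = 60.0) -> tuple[float, float]:
    """Field position (µm from FOV center) of the brightest structure near
    the center — where the instrument would park the guide star."""
    mip = ph.density.max(axis=0)
    ny, nx = mip.shape
    dy, dx = ph.voxel_um[1], ph.voxel_um[2]
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um = (xx + 0.5) * dx - nx * dx / 2
    y_um = (yy + 0.5) * dy - ny * dy / 2
    central = np.hypot(x_um, y_um) <= search_radius_um
    masked = np.where(central, mip, -1.0)
    iy, ix = np.unravel_index(int(masked.argmax()), mip.shape)
    return float(x_um[iy, ix]), float(y_um[iy, ix])


def sensing_area_tradeoff(
    seed: int = 1,
    fov_um: float = 580.0,
    area_sides_um: tuple[float, ...] | list[float] = (19.0, 95.0, 190.0, 380.0),
    out_dir: str | Path | None = None,
    px_um: float = 4.0,
    tiles: int = 7,
    grid: PupilGrid | None = None,
) -> pd.DataFrame:
    """Run AO at several wavefront-sensing area sizes on one synthetic eye.

    For each area side: sense the area-averaged wavefront at the field of
    view center (noiseless), reconstruct, fit the corrective wavefront to
    the 163-segment mirror, render the AO stack, and quantify it against
    the shared No-AO render with a ratio map and radial profile.  Returns
    a summary table (one row per area) with the peak gain and effective
    radius; optionally writes ratio maps and profiles under ``out_dir``.
    """
    grid = grid or PupilGrid(128)
    # the eye's aberration field extends beyond the imaged area, so the
    # guide-star scan may wander past the FOV edge without a range error
    eye = sample_ocular_aberration(seed, fov_um=fov_um + 160.0)
    ph = make_vessel_phantom(
        VesselConfig(
            size_um=(fov_um, fov_um, 24.0),
            voxel_um=2.0,
            plexus_depths_um=(6.0, 12.0, 18.0),
            n_large=4,
            n_capillaries=10,
        ),
        seed=seed,
    )
    cfg = ImagingConfig(
        fov_um=fov_um, px_um=px_um, dz_um=4.0, tiles=tiles, seed=seed,
        psf_halfdepth_um=8.0,
    )
    dm = build_hex_layout()
    arr = LensletArray()
    noao = render_stack(ph, eye, dm=None, cfg=cfg)
    center = _brightest_central_spot(ph, search_radius_um=60.0)
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    for side in area_sides_um:
        slopes = sense_guide_star(
            ph, eye, None, None, center, side, arr, seed=seed, grid=grid
        )
        rec = reconstruct_modal(slopes, grid=grid)
        corr = corrective_from_measurement(rec)
        fitted = fit_dm(corr, dm)
        ao = render_stack(ph, eye, dm=fitted, cfg=cfg)
        rm = ratio_map(ao, noao)
        prof = radial_profile(rm, center_um=center)
        rows.append(
            {
                "area_side_um": side,
                "peak_gain": float(rm.map.max()),
                "center_gain": float(prof.mean_ratio[0]),
                "effective_radius_um": prof.effective_radius_um,
            }
        )
        if out is not None:
            import tifffile

            tifffile.imwrite(out / f"ratio_map_{side:g}um.tif", rm.map.astype(np.float32))
            pd.DataFrame(
                {"radius_um": prof.radii_um, "mean_ratio": prof.mean_ratio}
            ).to_csv(out / f"radial_profile_{side:g}um.csv", index=False)
    summary = pd.DataFrame(rows)
    if out is not None:
        summary.to_csv(out / "summary.csv", index=False)
    return summary
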