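"""Measure a synthetic ocular aberration with the Shack-Hartmann model and
reconstruct the wavefront two ways.

The lenslet array turns local wavefront slopes into spot displacements on
a camera; centroiding the spots and differencing against the flat-
wavefront reference gives a slope field, which is integrated either
zonally (Southwell least squares) or modally (Zernike-gradient fit).
"""

import numpy as np

from retao import (
    LensletArray,
    PupilGrid,
    compose,
    find_centroids,
    reconstruct_modal,
    reconstruct_zonal,
    render_sh_frame,
    rms,
    sample_ocular_aberration,
    slopes_from_centroids,
)
from retao.shwfs import reference_frame

grid = PupilGrid(256)
arr = LensletArray()  # 16 subapertures across, 16 px windows
eye = sample_ocular_aberration(seed=3)
w = compose(eye.base_coeffs, grid)
print(f"true aberration rms: {rms(w):.3f} µm")

frame = find_centroids(render_sh_frame(w, arr, photons=5000, seed=0))
ref = find_centroids(reference_frame(grid, arr))
slopes = slopes_from_centroids(frame, ref, arr)
print(f"valid subapertures: {int(slopes.valid.sum())}")

for rec in (reconstruct_modal(slopes, grid=grid), reconstruct_zonal(slopes, grid=grid)):
    err = rms(rec.wavefront - w)
    print(f"{rec.method:>5s} reconstruction error: {err:.4f} µm "
          f"({100 * err / rms(w):.1f}% of input)")
# Both estimators recover the wavefront to a few percent at this photon
# budget; the residual sets how well the mirror can cancel the aberration.
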