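"""Build wavefronts from Zernike modes, decompose them, and report rms/P-V.

A wavefront is an optical-path map in µm over the unit pupil; Noll-indexed
unit-rms Zernike modes are its modal currency (j=1 piston, 2-3 tip/tilt,
4 defocus, 5-25 the higher aberrations this instrument corrects).
"""

import numpy as np

from retao import PupilGrid, ZernikeCoeffs, compose, decompose, pv, remove_modes, rms

grid = PupilGrid(256)
coeffs = np.zeros(25)
coeffs[3] = 0.4   # defocus, µm rms
coeffs[10] = 0.2  # primary spherical aberration
w = compose(ZernikeCoeffs(coeffs), grid)
print(f"composed wavefront: rms = {rms(w):.3f} µm, P-V = {pv(w):.3f} µm")

recovered = decompose(w, 25)
print(f"decomposed: defocus {recovered[4]:+.3f} µm, spherical {recovered[11]:+.3f} µm")

stripped = remove_modes(w, {1, 2, 3, 4})
print(f"after removing piston/tip/tilt/defocus: rms = {rms(stripped):.3f} µm")
# The leftover rms is exactly the spherical term: removing the low modes is
# how reported aberration magnitudes are standardized.
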