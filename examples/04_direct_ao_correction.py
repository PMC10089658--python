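"""Run one closed loop of direct-wavefront-sensing AO on a synthetic eye.

A guide star scanned over a 19×19 µm² patch of a vascular phantom is
sensed through the eye's aberration; the reconstructed wavefront is
negated, stripped of tip/tilt, and fitted to the 163-segment mirror.
The report compares Strehl at the sensing site before and after.
"""

from retao import PupilGrid, run_direct_ao, sample_ocular_aberration
from retao.psf import OpticalConfig
from retao.synth import VesselConfig, make_vessel_phantom

phantom = make_vessel_phantom(VesselConfig(size_um=(120, 120, 24), voxel_um=2.0), seed=1)
eye = sample_ocular_aberration(seed=1, fov_um=240.0)

result = run_direct_ao(
    phantom, eye,
    area_center_um=(0.0, 0.0), area_side_um=19.0,
    grid=PupilGrid(128), opt=OpticalConfig(pad_factor=4),
)

print(f"correction accepted: {result.accepted}")
print(f"Strehl at sensing site: {result.metric_before:.2e} -> {result.metric_after:.3f}")
print(f"residual wavefront rms: {result.diagnostics['residual_rms_um']:.4f} µm")
# A single noiseless iteration typically removes >90% of the wavefront rms,
# lifting Strehl from deep-speckle levels back toward the diffraction limit.
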