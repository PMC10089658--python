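# Methods

## Wavefronts and the Zernike basis

All aberrations are optical-path maps in µm over the unit pupil, sampled
on a square grid (default 256 samples across the pupil diameter; all
stated tolerances refer to this resolution). The modal basis is
Noll-indexed (j = 1 piston, 2–3 tip/tilt, 4 defocus) with unit-rms
normalization, so a coefficient of c µm means that mode alone carries
c µm rms over the pupil; "the first 21 modes excluding piston, tip, tilt
and defocus" is therefore Noll j = 5…25. No convention is forced by the
instrument itself; Noll + unit-rms is the adaptive-optics community
default and makes sweep amplitudes in µm rms map directly onto
coefficients. `rms` is piston-free (mask mean removed); `pv` is max −
min over the mask. Mode removal is a least-squares projection onto the
span of exactly the listed modes, so the residual is orthogonal to each
removed mode to solver precision even though the discretized basis is
only orthonormal to ~1e−3.

Phase maps are stored over the full square array (Zernike polynomials
evaluate fine at ρ > 1); statistics only ever look inside the mask. This
keeps finite-difference gradients clean up to the pupil rim, which the
Shack–Hartmann forward model relies on.

## PSF engine

Scalar Fourier optics: I(x, z) ∝ |FFT{P exp(i 2π W/λ + i φ_z)}|², with
P the unit disk, W the aberration in µm, and the defocus phase in the
high-NA spherical-cap convention φ_z = (2π/λ) z √(n² − NA² ρ²). Scalar
(not vectorial) diffraction is adequate at NA 0.49 for FWHM-level
quantities; the spherical (not paraxial ρ²) defocus convention matters at
this NA — the axial FWHM is sensitive to it. Defaults: NA 0.49, λ =
0.92 µm, n = 1.33, zero-padding 8× (image-plane sampling λ/(2·NA·pad) ≈
0.117 µm). Aberrated intensities are normalized to the unaberrated peak,
so the map maximum is the Strehl ratio. A guard rejects pupils whose
per-sample phase step exceeds π (aliased focal field). On-axis intensity
is also available as a direct phasor sum (no FFT), which is how axial
profiles are measured at 0.1 µm steps cheaply; the two paths agree to
1e−6 (tested).

The two-photon effective PSF is the pointwise square of the excitation
intensity — the quantity that sets both resolution and signal in
two-photon imaging. At the defaults this measures 0.70 µm lateral and
6.28 µm axial FWHM (baseline = profile minimum, half-crossings by linear
interpolation).

## Shack–Hartmann model

Subapertures are an n×n grid over the pupil (default 16 across,
comparable to the ~14 mirror segments across the pupil). The measured
quantity per subaperture is the mean wavefront gradient over its in-mask
samples (samples binned by coordinate so cell boundaries sit exactly on
subaperture edges). Spots are Gaussians of fixed σ (1.5 px) displaced by
focal_px × slope in 16 px windows; focal_px defaults to 3/(4√3) px per
(µm/pupil-unit) so 1 µm rms of defocus moves rim spots ~3 px. Spots whose
displacement would leave the window are dark and invalid (a distorted or
vignetted focus); a subaperture is illuminated when ≥ 50% of its area is
inside the pupil. Photon noise is Poisson with a configurable expected
count at the brightest spot; 0 means noiseless.

Centroiding: per-window median background subtraction, negatives clipped,
center of mass; a window is valid iff its background-subtracted peak
exceeds 10% of the frame's brightest window. The reference frame is the
noiseless render of the zero wavefront (the post-system-correction
reference). Noiseless centroids are good to ~1e−3 px; at 1000
photons/spot the median error stays below 0.2 px (tested over 50 seeds).

## Reconstruction

**Modal** (default in the AO loop): least squares of the per-subaperture
mean gradients of modes 2…25 against the measured slopes. The mode
gradients are built with the same subaperture-averaging operator as the
measurement model, so inversion is consistent; piston has no gradient and
is pinned to 0. Rank problems raise a conditioning error with the
condition number.

**Zonal**: Southwell geometry (phase nodes co-located with the slope
samples), dense least squares (≤ ~500 unknowns), piston pinned by a
zero-mean row, solved on the largest connected component of valid
subapertures. Two O(h²) systematic errors are corrected: subaperture-mean
slopes are converted to center point slopes via a finite-difference
Laplacian (stencils shift inward at the rim), and each Southwell link
uses the trapezoid rule plus a third-difference correction (O(h⁵) link
error; the stencil again shifts inward at the rim). Node values are
resampled to the pupil grid with bicubic Hermite patches built from the
solved phases, the measured slopes and finite-difference cross
derivatives; rim samples evaluate the nearest complete cell's patch. With
point-sampled gradients of the primary-spherical mode at 16 subapertures
across, the reconstructed map matches the mode to 0.4% rms; through the
full cell-averaged pipeline, smooth 21-mode wavefronts come back to 2–4%.

**Corrective wavefront**: the negated reconstruction with piston/tip/tilt
projected out — tip and tilt redirect the focus rather than blur it.
Measured defocus is kept in the correction by default (a flag strips it
for instruments that leave focus to the tunable lens); magnitudes quoted
for aberrations, by contrast, always remove tip/tilt/defocus.

## Segmented mirror

The 163-segment piston/tip/tilt device is modeled as a 7-ring hexagonal
tiling (169 segments) minus the six outermost corner segments — the
minimal regular layout reproducing the segment count, which the
instrument reports without an arrangement drawing. Pitch is 1/7 of the
pupil radius so the central segment row spans the pupil. Segment
ownership is nearest-center (exact hexagonal Voronoi); samples outside
all segments take the nearest segment's plane. Fitting a target is an
independent least-squares plane fit per segment (no inter-segment
continuity — a true segmented mirror), which makes the fit linear and
idempotent; segments with fewer than 3 in-mask samples are flagged and
assigned the mean plane of their ≤1.5-pitch neighbors. Stroke is
unlimited by default (no saturation is modeled). Fitting 1 µm rms of
defocus leaves 0.007 µm rms of residual.

## Synthetic eye and field dependence

One eye = one seed. Base coefficients on Noll 5–25 are drawn with
per-mode standard deviation ∝ 1/n(j)² (radial order; the instrument's
literature gives aggregate rms/P-V, not a spectrum — the 1/n² decay is a
smoothness assumption), then rescaled so the rms over modes 5–25 is a
Uniform(0.45, 0.75) µm draw. Over 100 seeds the ensemble median is
0.59 µm rms and 4.0 µm P-V (both with low modes removed), inside the
characterized 0.4–0.8 µm / ≤5 µm band.

Field dependence multiplies each mode by (1 + a·f_j(x, y)), where f_j is
an independent stationary unit-variance random-cosine field (8 features,
wavenumbers 0.5–1.5 per correlation length). Correlation length defaults
to 200 µm — chosen to echo the few-hundred-µm effective correction radii
the technique reports on a 580 µm field — and the relative amplitude a
defaults to 1.2. The amplitude is deliberately > 1: the defining
qualitative behavior of this instrument class is that a correction
measured at one field point *degrades* the image beyond a few hundred µm
(pixel ratio < 1), which requires the aberration at decorrelated field
points to differ by more than the shared component a center correction
removes. With a = 1.2 the rms difference between field points grows with
separation, saturates beyond the correlation length, and exceeds the
local aberration at FOV-corner separations. No quantitative field-model
is published for the mouse eye; both parameters are exposed.

The ETL adds Δz = 5 µm/mA × current of focal shift (the true slope is
not printed; 5 µm/mA puts the 10–60 mA working range at a retina-scale
~250 µm) as the same spherical-cap defocus OPD the PSF engine uses, so
ETL defocus and axial propagation compose exactly and doubling the
current doubles the shift identically. Parasitic aberration is a
per-mA Zernike vector, zero by default.

## Phantoms and calcium traces

Phantoms are noiseless fluorophore-density volumes with integer structure
labels (vessel lumen/wall, soma, process, varicosity, lesion wall, leak);
noise enters only at image rendering. Vessels: persistent random-walk
tubes in three laminar plexuses (large vessels 8–15 µm in the superficial
plexus, capillaries 3–5 µm in all), with lumen-filling (dye) or
wall-only (endothelial reporter) labeling. Neurons: soma spheres
(6–10 µm) in two nuclear layers separated by a process-only layer;
≤1 µm processes decorated with 1–2 µm varicosities. Lesion: a
wall-labeled capillary stub whose end face is open (an annulus in
cross-section, verified by a connectivity audit) with an optional
extravascular leak blob. Default volumes are 120×120×64 µm³ at 1 µm
voxels; the trade-off experiment uses FOV-sized volumes at 2 µm voxels.

Calcium traces: per cell, a hyperactive baseline rate (8 Hz × cell factor
with slow sinusoidal drift) gated by the protocol — ×(1 − depth) during
suppression, ×(1 − depth·(1 − recovery)) after — drives Poisson spikes
convolved with an exponential indicator kernel (τ = 1.5 s), scaled and
offset to a strictly positive fluorescence. ΔF/F uses F₀ = 10th
percentile of the raw trace over the treatment window by default.

## Image formation

Stacks are rendered with a piecewise field-varying PSF: the field splits
into tiles (5×5 default; the trade-off experiment uses 7×7 to resolve the
correction falloff), each tile's effective wavefront is eye(tile center)
+ ETL + DM surface, its two-photon PSF is cropped (±8 µm lateral,
±12 µm axial), pixel-area-integrated onto the stack voxel grid, and the
density volume is convolved per tile; tiles blend with triangular seam
weights. Kernels are scaled by the *unaberrated* kernel's integral — not
each kernel's own — so aberrated tiles render genuinely dimmer, as
two-photon signal does. Rendering uses a 128-sample pupil with 4×
padding (µm-scale voxels don't need the metrology resolution). Poisson
noise applies at a configurable photons-per-unit; phantom and PSF
downsampling are box-prefiltered to avoid aliasing away sub-voxel peaks.

Guide-star sensing returns the slopes of the area-averaged wavefront:
the mean of the field-dependent aberration over 5×5 scan points in the
sensing area (19 µm side by default) plus ETL and DM terms, rendered
through the full Shack–Hartmann chain. Sensing a region with no labeled
fluorophores raises a dim-frame error, mirroring failed sensing on empty
retina. Depth structure of the scanned patch is ignored (single-plane
sensing).

## AO procedures

Direct AO is single-iteration by default, as in the instrument's
workflow: sense → reconstruct (modal, 25 modes) → negate & strip tip/tilt
→ fit to the mirror → evaluate. The before/after metric is the Strehl
ratio of the effective wavefront at the sensing-area center; a correction
that lowers it is rejected and the mirror stays flat, so the loop never
applies a worsening correction.

The modal sweep evaluates every amplitude for every mode (11 × 21 = 231
metric calls), applying each mode's argmax before the next mode. Ties
break toward the smallest |amplitude| (evaluation order is sorted by
|amplitude| with a strict improvement test), so a flat metric leaves a
mode untouched and a perfect system selects all zeros. The bundled
metric is Σ I² of the excitation PSF — the simulated total two-photon
fluorescence of a thin uniform sample — but any deterministic
`f(ZernikeCoeffs) → float` works.

## Numerical choices and problem sizes

- Default pupil grid 256 (metrology), 128 (rendering, sweeps); FFT pad 8
  (metrology) / 4 (rendering).
- The acceptance script draws 100 eyes for ensemble medians and measures
  the PSF at 256 pupil samples / 8× padding, axially at 0.1 µm steps over
  ±15 µm. The test suite's closed-loop check runs 20 eyes; phantom audits
  run 20 seeds; the trade-off experiment renders a 580 µm FOV at 4 µm
  pixels with 7×7 tiles.
- Dense `lstsq` everywhere (largest system ~500 unknowns); no iterative
  solvers.
- Degenerate inputs: empty pupil masks, flat/monotone FWHM profiles,
  dark sensing areas, all-invalid frames, rank-deficient modal systems
  and disconnected zonal domains all raise typed errors (or flag and
  continue where the operation's contract calls for that instead).

## What the synthetic twin does and does not show

The generator reproduces the *structure* of the measurement problem:
aberration magnitudes and smoothness, field decorrelation, segmented-DM
fitting limits, photon-limited centroiding, the averaging effect of the
sensing area, and epoch structure in calcium traces. It does not model
eye motion, photoreceptor optics, hemodynamics, scattering, detector
fixed-pattern noise, or pharmacokinetics — so passing tests demonstrate
the correctness and internal consistency of the computational pipeline,
not in-vivo performance. Headline in-vivo numbers (specific fold-changes,
exact effective radii) are emergent properties of real eyes; here the
corresponding checks are qualitative orderings (gain peaks at the sensing
site and decays with field radius; small-area vs large-area sensing
trades peak gain for corrected field size) plus the desk-scale
quantitative bands above.

## Known limitations

- The zonal path through cell-averaged slopes is a few times less
  accurate than the modal path on smooth inputs; the AO loop uses modal
  by default.
- Piecewise-constant-per-tile PSFs quantize the field variation; tile
  counts below ~7 blur the sensing-area trade-off near the sensing site.
- The hexagonal segment arrangement is a documented guess constrained
  only by the 163-segment count.
- The guide star is treated as planar; 3D structure of the scanned patch
  is ignored.
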