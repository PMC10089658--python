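"""Synthetic study material: mouse ocular aberrations with field
dependence, an electrically-tunable-lens focus model, 3D retinal phantoms
(vascular plexuses, neurons, capillary lesions) and calcium time series.

Everything here is seeded and deterministic: identical seeds give
bit-identical outputs.  The aberration generator is calibrated to the
characterized band of mouse ocular aberrations — after removing piston,
tip, tilt and defocus, rms in roughly 0.4–0.8 µm and peak-to-valley within
about 5 µm — with per-mode variance decaying as 1/(radial order)² over
Noll modes 5–25.  Field dependence is a smooth stationary random field
with a configurable correlation length, standing in for the gradient-index
optics of the eye for which no quantitative model is published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .psf import OpticalConfig, _defocus_opd
from .zernike import (
    PupilGrid,
    Wavefront,
    ZernikeCoeffs,
    compose,
    noll_to_nm,
)

__all__ = [
    "EyeModel",
    "ETLState",
    "Phantom",
    "CalciumSeries",
    "CalciumProtocol",
    "sample_ocular_aberration",
    "aberration_at_field",
    "apply_etl",
    "VesselConfig",
    "NeuronConfig",
    "LesionConfig",
    "make_vessel_phantom",
    "make_neuron_phantom",
    "make_lesion_phantom",
    "make_calcium_series",
]

EYE_MODES = tuple(range(5, 26))  # Noll modes 5..25: first 21 excluding piston/tip/tilt/defocus
_N_FOURIER = 8  # random-cosine features per mode for the field model


@dataclass
class EyeModel:
    """Field-dependent ocular aberration generator state.

    base_coeffs holds Noll modes 1..25 (only 5..25 nonzero).  The
    aberration at field position (x, y) µm is the base plus a smooth
    perturbation per mode; ``field_amp_rel`` scales the perturbation
    relative to each base coefficient, and ``field_corr_um`` sets the
    correlation length of the variation.
    """

    base_coeffs: ZernikeCoeffs
    field_amp_rel: float
    field_corr_um: float
    fov_um: float
    seed: int
    # random-cosine field parameters: (n_modes, K) each
    _wavevec: np.ndarray = field(repr=False, default=None)  # (n_modes, K, 2)
    _phases: np.ndarray = field(repr=False, default=None)  # (n_modes, K)
    _weights: np.ndarray = field(repr=False, default=None)  # (n_modes, K)

    def rms(self) -> float:
        """Base rms over modes 5-25 (orthonormal basis: the coefficient norm)."""
        return float(np.linalg.norm(self.base_coeffs.coeffs[4:]))


@dataclass(frozen=True)
class ETLState:
    """Electrically tunable lens: focal shift strictly linear in current.

    The default slope (5 µm of focal shift per mA) puts the 10–60 mA
    working range at retina scale (~250 µm).  parasitic_coeffs are small
    Zernike amplitudes added per mA of drive, off by default at a
    measured-negligible level.
    """

    current_ma: float = 0.0
    um_per_ma: float = 5.0
    parasitic_per_ma: tuple[float, ...] = ()  # Noll 1.. amplitudes per mA

    @property
    def focal_shift_um(self) -> float:
        return self.um_per_ma * self.current_ma


@dataclass
class Phantom:
    """3D fluorophore density with integer structure labels.

    Label codes: 0 background, 1 vessel lumen, 2 vessel wall, 3 soma,
    4 process, 5 varicosity, 6 lesion wall, 7 leak.
    """

    density: np.ndarray  # (z, y, x), arbitrary units, >= 0
    labels: np.ndarray
    voxel_um: tuple[float, float, float]  # (dz, dy, dx)
    meta: dict = field(default_factory=dict)

    LABEL = {
        "background": 0,
        "lumen": 1,
        "wall": 2,
        "soma": 3,
        "process": 4,
        "varicosity": 5,
        "lesion_wall": 6,
        "leak": 7,
    }


@dataclass
class CalciumSeries:
    """Per-cell fluorescence traces plus the generating ground truth."""

    t_s: np.ndarray
    f: np.ndarray  # (n_cells, n_t), strictly positive
    truth_rate: np.ndarray  # (n_cells, n_t) underlying spike rate (Hz)
    protocol: "CalciumProtocol"


@dataclass(frozen=True)
class CalciumProtocol:
    """Suppression protocol: epoch boundaries in seconds and effect sizes.

    Emulates an acute pharmacological silencing experiment: a hyperactive
    baseline epoch, a suppression epoch (rate × (1 − depth)), and a
    recovery epoch where a configured fraction of the lost rate returns.
    """

    t_before_s: float = 60.0
    t_during_s: float = 60.0
    t_after_s: float = 60.0
    depth: float = 0.9
    recovery: float = 0.5
    fs_hz: float = 10.0

    @property
    def total_s(self) -> float:
        return self.t_before_s + self.t_during_s + self.t_after_s

    def epoch_slices(self, n: int) -> dict[str, slice]:
        i1 = int(round(self.t_before_s * self.fs_hz))
        i2 = i1 + int(round(self.t_during_s * self.fs_hz))
        return {"before": slice(0, i1), "during": slice(i1, i2), "after": slice(i2, n)}


# ---------------------------------------------------------------- aberrations


def sample_ocular_aberration(
    seed: int,
    rms_range_um: tuple[float, float] = (0.45, 0.75),
    field_amp_rel: float = 1.2,
    field_corr_um: float = 200.0,
    fov_um: float = 580.0,
) -> EyeModel:
    """Draw one synthetic mouse eye.

    Per-mode variance decays as 1/n(j)² with radial order n(j); the draw is
    rescaled so its rms over modes 5–25 is Uniform(rms_range) µm.  The
    ensemble median then sits inside the characterized 0.4–0.8 µm band
    with median peak-to-valley below ~5 µm.
    """
    rng = np.random.default_rng(seed)
    sigma = np.array([1.0 / noll_to_nm(j)[0] ** 2 for j in EYE_MODES])
    raw = rng.standard_normal(len(EYE_MODES)) * sigma
    target = rng.uniform(*rms_range_um)
    raw *= target / np.linalg.norm(raw)
    coeffs = np.zeros(26)
    coeffs[np.array(EYE_MODES) - 1] = raw
    coeffs = coeffs[:25]
    k = rng.uniform(0.5, 1.5, size=(len(EYE_MODES), _N_FOURIER))
    ang = rng.uniform(0, 2 * np.pi, size=(len(EYE_MODES), _N_FOURIER))
    wavevec = np.stack([k * np.cos(ang), k * np.sin(ang)], axis=-1)
    phases = rng.uniform(0, 2 * np.pi, size=(len(EYE_MODES), _N_FOURIER))
    weights = rng.standard_normal((len(EYE_MODES), _N_FOURIER)) / np.sqrt(_N_FOURIER / 2)
    return EyeModel(
        ZernikeCoeffs(coeffs),
        field_amp_rel,
        field_corr_um,
        fov_um,
        seed,
        wavevec,
        phases,
        weights,
    )


def _field_perturbation(eye: EyeModel, x_um: float, y_um: float) -> np.ndarray:
    """Zero-mean unit-variance stationary field per mode, evaluated at (x, y)."""
    u = np.array([x_um, y_um]) / eye.field_corr_um
    args = eye._wavevec @ u + eye._phases  # (n_modes, K)
    return (eye._weights * np.cos(args)).sum(axis=1)


def aberration_at_field(eye: EyeModel, x_um: float, y_um: float, grid: PupilGrid | None = None) -> Wavefront:
    """Ocular aberration at a retinal field position (µm from FOV center).

    Deterministic in (eye.seed, x, y).  The expected rms difference
    between two field points grows with separation and saturates beyond
    the correlation length.
    """
    half = eye.fov_um / 2.0
    if abs(x_um) > half or abs(y_um) > half:
        raise ValueError(
            f"field point ({x_um}, {y_um}) outside the ±{half} µm field of view"
        )
    grid = grid or PupilGrid()
    base = eye.base_coeffs.coeffs.copy()
    if eye.field_amp_rel > 0:
        pert = _field_perturbation(eye, x_um, y_um)
        idx = np.array(EYE_MODES) - 1
        base[idx] = base[idx] * (1.0 + eye.field_amp_rel * pert)
    return compose(ZernikeCoeffs(base), grid)


def apply_etl(w: Wavefront, etl: ETLState, cfg: OpticalConfig | None = None) -> Wavefront:
    """Add the tunable lens's contribution to a wavefront.

    The focal shift Δz = um_per_ma × current adds the defocus optical path
    Δz·√(n² − NA²ρ²) (the same spherical-cap convention the PSF engine
    uses, so ETL defocus and axial propagation compose exactly), plus any
    parasitic aberration scaled by the current.
    """
    cfg = cfg or OpticalConfig()
    dz = etl.focal_shift_um
    phase = w.phase + dz * _defocus_opd(w.grid, cfg)
    if etl.parasitic_per_ma:
        c = np.asarray(etl.parasitic_per_ma) * etl.current_ma
        phase = phase + compose(ZernikeCoeffs(c), w.grid).phase
    return Wavefront(w.grid, phase)


# ------------------------------------------------------------------ phantoms


@dataclass(frozen=True)
class VesselConfig:
    """Three-plexus retinal vasculature."""

    size_um: tuple[float, float, float] = (120.0, 120.0, 64.0)  # (x, y, z)
    voxel_um: float = 1.0
    plexus_depths_um: tuple[float, ...] = (8.0, 30.0, 52.0)
    n_large: int = 3  # large vessels in the superficial plexus
    n_capillaries: int = 6  # per plexus
    large_diam_um: tuple[float, float] = (8.0, 15.0)
    cap_diam_um: tuple[float, float] = (3.0, 5.0)
    wall_only: bool = False  # endothelium labeling vs lumen-filling dye
    wall_um: float = 1.0


@dataclass(frozen=True)
class NeuronConfig:
    """Two nuclear layers separated by a process-only (plexiform) layer."""

    size_um: tuple[float, float, float] = (120.0, 120.0, 64.0)
    voxel_um: float = 1.0
    layer_depths_um: tuple[float, float] = (12.0, 48.0)
    layer_halfwidth_um: float = 6.0
    n_somata_per_layer: int = 8
    soma_diam_um: tuple[float, float] = (6.0, 10.0)
    n_processes: int = 10
    process_radius_um: float = 0.5
    n_varicosities: int = 30
    varicosity_diam_um: tuple[float, float] = (1.0, 2.0)


@dataclass(frozen=True)
class LesionConfig:
    """Wall-labeled capillary stub open at its end face (a laser lesion site)."""

    size_um: tuple[float, float, float] = (60.0, 60.0, 40.0)
    voxel_um: float = 1.0
    stub_length_um: float = 24.0
    stub_diam_um: float = 8.0
    wall_um: float = 1.5
    leak: bool = True
    leak_sigma_um: float = 8.0
    leak_amplitude: float = 0.3


def _empty_volume(size_um, voxel_um):
    nx = int(round(size_um[0] / voxel_um))
    ny = int(round(size_um[1] / voxel_um))
    nz = int(round(size_um[2] / voxel_um))
    density = np.zeros((nz, ny, nx), dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    return density, labels


def _paint_tube(density, labels, path_vox, radius_vox, value, label, wall_vox=None):
    """Paint spheres along a polyline; wall_vox paints only the shell."""
    nz, ny, nx = density.shape
    r = int(np.ceil(radius_vox)) + 1
    for p in path_vox:
        z0, y0, x0 = (int(round(c)) for c in p)
        if not (-r <= z0 < nz + r and -r <= y0 < ny + r and -r <= x0 < nx + r):
            continue
        zs = slice(max(z0 - r, 0), min(z0 + r + 1, nz))
        ys = slice(max(y0 - r, 0), min(y0 + r + 1, ny))
        xs = slice(max(x0 - r, 0), min(x0 + r + 1, nx))
        zz, yy, xx = np.mgrid[zs, ys, xs]
        d = np.sqrt((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
        if wall_vox is None:
            sel = d <= radius_vox
        else:
            sel = (d <= radius_vox) & (d > radius_vox - wall_vox)
        density[zs, ys, xs][sel] = value
        labels[zs, ys, xs][sel] = label


def _wiggly_path(rng, n_pts, start, direction, step_vox, z_jitter=0.3):
    """Random-walk polyline (z, y, x) with a persistent in-plane heading."""
    pos = np.array(start, dtype=float)
    ang = np.arctan2(direction[1], direction[0])
    path = [pos.copy()]
    for _ in range(n_pts - 1):
        ang += rng.normal(0, 0.25)
        pos = pos + np.array(
            [rng.normal(0, z_jitter), np.sin(ang) * step_vox, np.cos(ang) * step_vox]
        )
        path.append(pos.copy())
    return path


def make_vessel_phantom(cfg: VesselConfig | None = None, seed: int = 0) -> Phantom:
    """Branching three-plexus vascular phantom.

    Large vessels (8–15 µm) populate the superficial plexus; capillaries
    (3–5 µm) run in every plexus near its configured depth.  wall_only
    labels only the endothelial shell (wall label) instead of filling the
    lumen (dye label).
    """
    cfg = cfg or VesselConfig()
    rng = np.random.default_rng(seed)
    density, labels = _empty_volume(cfg.size_um, cfg.voxel_um)
    nz, ny, nx = density.shape
    segments = []  # (diameter_um, kind)
    lum_label = Phantom.LABEL["wall"] if cfg.wall_only else Phantom.LABEL["lumen"]
    wall_vox = cfg.wall_um / cfg.voxel_um if cfg.wall_only else None
    for pi, depth in enumerate(cfg.plexus_depths_um):
        z0 = depth / cfg.voxel_um
        vessels = []
        if pi == 0:
            for _ in range(cfg.n_large):
                vessels.append(rng.uniform(*cfg.large_diam_um))
        for _ in range(cfg.n_capillaries):
            vessels.append(rng.uniform(*cfg.cap_diam_um))
        for diam in vessels:
            start = (z0, rng.uniform(0, ny), rng.uniform(0, nx))
            heading = rng.uniform(0, 2 * np.pi)
            path = _wiggly_path(
                rng,
                n_pts=int(1.2 * max(ny, nx)),
                start=start,
                direction=(np.sin(heading), np.cos(heading)),
                step_vox=1.0,
            )
            _paint_tube(
                density,
                labels,
                path,
                radius_vox=diam / 2 / cfg.voxel_um,
                value=1.0,
                label=lum_label,
                wall_vox=wall_vox,
            )
            segments.append((diam, "large" if diam >= cfg.cap_diam_um[1] else "capillary"))
    meta = {"seed": seed, "segments": segments, "config": cfg}
    v = cfg.voxel_um
    return Phantom(density, labels, (v, v, v), meta)


def make_neuron_phantom(cfg: NeuronConfig | None = None, seed: int = 0) -> Phantom:
    """Fluorescent-neuron phantom: somata in two nuclear layers, thin
    processes crossing the plexiform layer between them, decorated with
    bright varicosities (putative synaptic structures)."""
    cfg = cfg or NeuronConfig()
    rng = np.random.default_rng(seed)
    density, labels = _empty_volume(cfg.size_um, cfg.voxel_um)
    nz, ny, nx = density.shape
    soma_centers = []
    for depth in cfg.layer_depths_um:
        for _ in range(cfg.n_somata_per_layer):
            zc = (depth + rng.uniform(-cfg.layer_halfwidth_um, cfg.layer_halfwidth_um)) / cfg.voxel_um
            yc, xc = rng.uniform(0, ny), rng.uniform(0, nx)
            r = rng.uniform(*cfg.soma_diam_um) / 2 / cfg.voxel_um
            _paint_tube(density, labels, [(zc, yc, xc)], r, 1.0, Phantom.LABEL["soma"])
            soma_centers.append((zc * cfg.voxel_um, yc * cfg.voxel_um, xc * cfg.voxel_um))
    process_pts = []
    z_lo = cfg.layer_depths_um[0] / cfg.voxel_um
    z_hi = cfg.layer_depths_um[1] / cfg.voxel_um
    for _ in range(cfg.n_processes):
        start = (rng.uniform(z_lo, z_hi), rng.uniform(0, ny), rng.uniform(0, nx))
        heading = rng.uniform(0, 2 * np.pi)
        path = _wiggly_path(
            rng, n_pts=int(max(ny, nx)), start=start,
            direction=(np.sin(heading), np.cos(heading)), step_vox=1.0, z_jitter=0.15,
        )
        _paint_tube(
            density, labels, path,
            radius_vox=max(cfg.process_radius_um / cfg.voxel_um, 0.6),
            value=0.6, label=Phantom.LABEL["process"],
        )
        process_pts.extend(path)
    process_pts = np.array(process_pts)
    n_var = 0
    for _ in range(cfg.n_varicosities):
        p = process_pts[rng.integers(len(process_pts))]
        if not (0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx):
            p = np.clip(p, 0, [nz - 1, ny - 1, nx - 1])
        r = rng.uniform(*cfg.varicosity_diam_um) / 2 / cfg.voxel_um
        _paint_tube(density, labels, [p], max(r, 0.8), 1.5, Phantom.LABEL["varicosity"])
        n_var += 1
    v = cfg.voxel_um
    meta = {"seed": seed, "n_varicosities": n_var, "soma_centers_um": soma_centers, "config": cfg}
    return Phantom(density, labels, (v, v, v), meta)


def make_lesion_phantom(cfg: LesionConfig | None = None, seed: int = 0) -> Phantom:
    """Capillary-stub lesion: endothelium lines the wall of a short branch
    but not its end face, giving a ring in cross-section; optional
    extravascular leak density around the open end."""
    cfg = cfg or LesionConfig()
    rng = np.random.default_rng(seed)
    density, labels = _empty_volume(cfg.size_um, cfg.voxel_um)
    nz, ny, nx = density.shape
    zc, yc = nz // 2, ny // 2
    x0 = int(0.15 * nx)
    x1 = x0 + int(cfg.stub_length_um / cfg.voxel_um)  # open end face at x1
    r = cfg.stub_diam_um / 2 / cfg.voxel_um
    wall = cfg.wall_um / cfg.voxel_um
    zz, yy = np.mgrid[0:nz, 0:ny]
    d = np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2)
    ring = (d <= r) & (d > r - wall)
    for x in range(x0, min(x1, nx)):
        density[:, :, x][ring] = 1.0
        labels[:, :, x][ring] = Phantom.LABEL["lesion_wall"]
    # closed (origin) end face is capped: disc of wall at x0-1
    disc = d <= r
    if x0 - 1 >= 0:
        density[:, :, x0 - 1][disc] = 1.0
        labels[:, :, x0 - 1][disc] = Phantom.LABEL["lesion_wall"]
    if cfg.leak:
        zz3, yy3, xx3 = np.mgrid[0:nz, 0:ny, 0:nx]
        s = cfg.leak_sigma_um / cfg.voxel_um
        blob = cfg.leak_amplitude * np.exp(
            -((zz3 - zc) ** 2 + (yy3 - yc) ** 2 + (xx3 - x1) ** 2) / (2 * s**2)
        )
        outside = labels == 0
        add = blob * outside
        density += add.astype(np.float32)
        labels[(add > 0.01) & outside] = Phantom.LABEL["leak"]
    v = cfg.voxel_um
    meta = {"seed": seed, "open_face_x_vox": x1, "config": cfg}
    return Phantom(density, labels, (v, v, v), meta)


# ------------------------------------------------------------------- calcium


def make_calcium_series(
    n_cells: int = 10,
    protocol: CalciumProtocol | None = None,
    seed: int = 0,
    tau_s: float = 1.5,
    base_rate_hz: float = 8.0,
    f_offset: float = 20.0,
    f_gain: float = 10.0,
) -> CalciumSeries:
    """Hyperactive-cell calcium traces under a suppression protocol.

    Each cell's spike rate is a slowly fluctuating hyperactive baseline,
    multiplied by (1 − depth) during the suppression epoch and by
    (1 − depth·(1 − recovery)) in the recovery epoch; rates drive Poisson
    spikes convolved with an exponential indicator kernel (decay tau_s),
    scaled and offset into a strictly positive fluorescence trace.
    """
    protocol = protocol or CalciumProtocol()
    rng = np.random.default_rng(seed)
    n_t = int(round(protocol.total_s * protocol.fs_hz))
    dt = 1.0 / protocol.fs_hz
    t = np.arange(n_t) * dt
    sl = protocol.epoch_slices(n_t)
    gate = np.ones(n_t)
    gate[sl["during"]] = 1.0 - protocol.depth
    gate[sl["after"]] = 1.0 - protocol.depth * (1.0 - protocol.recovery)
    kernel_t = np.arange(0, 6 * tau_s, dt)
    kernel = np.exp(-kernel_t / tau_s)
    f = np.empty((n_cells, n_t))
    rates = np.empty((n_cells, n_t))
    for c in range(n_cells):
        slow = 1.0 + 0.3 * np.sin(2 * np.pi * t / rng.uniform(20, 60) + rng.uniform(0, 2 * np.pi))
        rate = base_rate_hz * rng.uniform(0.6, 1.4) * slow * gate
        rates[c] = rate
        spikes = rng.poisson(rate * dt)
        trace = np.convolve(spikes, kernel)[:n_t]
        f[c] = f_offset + f_gain * trace
    return CalciumSeries(t, f, rates, protocol)
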