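"""The two aberration-correction procedures.

``run_direct_ao`` is direct-wavefront-sensing AO: scan a two-photon guide
star over a sensing area, measure slopes with the Shack–Hartmann sensor,
reconstruct the wavefront, negate it (strip tip/tilt) and fit the result
to the segmented mirror.  A correction that does not improve the image
metric is rejected and the mirror stays flat.

``run_modal_system_correction`` is the sensorless modal sweep used for the
microscope's own (system) aberrations: for each Zernike mode in turn, try
a grid of amplitudes (default 11 values, −0.1…0.1 µm rms in 0.02 µm
steps) on top of the accumulated correction, keep the amplitude that
maximizes the fluorescence metric, and move to the next mode (default
Noll 5–25, the first 21 modes excluding piston, tip, tilt and defocus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dm import SegmentedDM, build_hex_layout, dm_to_wavefront, fit_dm
from .imaging import DimFrameError, effective_wavefront, sense_guide_star
from .psf import OpticalConfig, strehl
from .reconstruct import ReconstructionResult, corrective_from_measurement, reconstruct_modal, reconstruct_zonal
from .shwfs import LensletArray, SlopeField
from .synth import ETLState, EyeModel, Phantom
from .zernike import PupilGrid, Wavefront, ZernikeCoeffs, compose, rms

__all__ = [
    "ModalSweepConfig",
    "AOResult",
    "SweepError",
    "run_direct_ao",
    "run_modal_system_correction",
    "make_fluorescence_metric",
]


class SweepError(RuntimeError):
    """Non-finite metric during the modal sweep."""


@dataclass(frozen=True)
class ModalSweepConfig:
    """Sequential modal sweep: modes, amplitude grid, and metric tag."""

    mode_set: tuple[int, ...] = tuple(range(5, 26))
    amp_min_um: float = -0.1
    amp_max_um: float = 0.1
    amp_step_um: float = 0.02
    metric: str = "total-intensity"

    @property
    def amplitudes(self) -> np.ndarray:
        n = int(round((self.amp_max_um - self.amp_min_um) / self.amp_step_um)) + 1
        return self.amp_min_um + self.amp_step_um * np.arange(n)

    @property
    def n_evaluations(self) -> int:
        return len(self.amplitudes) * len(self.mode_set)


@dataclass
class AOResult:
    """Outcome of one direct-AO correction."""

    corrective: Wavefront
    dm_state: SegmentedDM
    metric_before: float
    metric_after: float
    slopes: SlopeField | None
    reconstruction: ReconstructionResult | None
    accepted: bool
    diagnostics: dict = field(default_factory=dict)


def run_direct_ao(
    ph: Phantom,
    eye: EyeModel,
    etl: ETLState | None = None,
    arr: LensletArray | None = None,
    area_center_um: tuple[float, float] = (0.0, 0.0),
    area_side_um: float = 19.0,
    dm: SegmentedDM | None = None,
    grid: PupilGrid | None = None,
    opt: OpticalConfig | None = None,
    photons: float = 0.0,
    seed: int = 0,
    method: str = "modal",
    n_modes: int = 25,
) -> AOResult:
    """Single-iteration direct-wavefront-sensing AO at a sensing area.

    The before/after metric is the Strehl ratio of the effective wavefront
    at the sensing-area center (the quantity image brightness follows as
    Strehl² in two-photon imaging).  If sensing fails on a dark area the
    loop aborts and returns the uncorrected state; if the correction would
    lower the metric it is rejected and the mirror stays flat.
    """
    arr = arr or LensletArray()
    grid = grid or PupilGrid()
    opt = opt or OpticalConfig()
    dm = dm or build_hex_layout()
    flat = dm.zeroed()
    cx, cy = area_center_um

    def center_strehl(dm_state: SegmentedDM) -> float:
        w = effective_wavefront(eye, dm_state, etl, cx, cy, grid, opt)
        return strehl(w, opt)

    metric_before = center_strehl(flat)
    try:
        slopes = sense_guide_star(
            ph, eye, flat, etl, area_center_um, area_side_um, arr,
            photons=photons, seed=seed, grid=grid,
        )
    except DimFrameError as err:
        return AOResult(
            Wavefront(grid, np.zeros((grid.n_samples,) * 2)), flat,
            metric_before, metric_before, None, None, False,
            {"aborted": str(err)},
        )
    if method == "modal":
        rec = reconstruct_modal(slopes, n_modes=n_modes, grid=grid)
    else:
        rec = reconstruct_zonal(slopes, grid=grid)
    corrective = corrective_from_measurement(rec)
    fitted = fit_dm(corrective, dm)
    metric_after = center_strehl(fitted)
    accepted = metric_after >= metric_before
    out_dm = fitted if accepted else flat
    residual = effective_wavefront(eye, out_dm, etl, cx, cy, grid, opt)
    return AOResult(
        corrective, out_dm, metric_before,
        metric_after if accepted else metric_before,
        slopes, rec, accepted,
        {"residual_rms_um": rms(residual)},
    )


def run_modal_system_correction(
    metric_fn,
    sweep: ModalSweepConfig | None = None,
) -> ZernikeCoeffs:
    """Sequential modal (sensorless) correction by metric maximization.

    ``metric_fn(coeffs: ZernikeCoeffs) -> float`` evaluates the image
    metric with the given correction applied.  For each mode in order, all
    grid amplitudes are tried on top of the accumulated correction and the
    argmax is kept before moving on (231 evaluations at the defaults).
    Ties break toward the smallest |amplitude|, so a flat metric leaves
    the mode untouched.
    """
    sweep = sweep or ModalSweepConfig()
    n = max(sweep.mode_set)
    acc = np.zeros(n)
    amps = sweep.amplitudes
    # evaluate smallest-|amplitude| first so strict ">" implements the tie-break
    order = np.argsort(np.abs(amps), kind="stable")
    for mode in sweep.mode_set:
        best_val = -np.inf
        best_amp = 0.0
        for k in order:
            a = amps[k]
            trial = acc.copy()
            trial[mode - 1] += a
            val = float(metric_fn(ZernikeCoeffs(trial)))
            if not np.isfinite(val):
                raise SweepError(f"non-finite metric at mode {mode}, amplitude {a:+.3f} µm")
            if val > best_val:
                best_val = val
                best_amp = a
        acc[mode - 1] += best_amp
    return ZernikeCoeffs(acc)


def make_fluorescence_metric(
    system_aberration: Wavefront,
    opt: OpticalConfig | None = None,
):
    """Metric factory for the modal sweep: total two-photon intensity.

    Returns a deterministic evaluator of sum(I²) of the excitation PSF of
    (hidden system aberration + trial correction) — the simulated
    fluorescence of a thin uniform test sample, maximized when the trial
    correction cancels the system aberration.
    """
    opt = opt or OpticalConfig(pad_factor=4)
    grid = system_aberration.grid

    def metric(coeffs: ZernikeCoeffs) -> float:
        from .psf import excitation_psf

        w = system_aberration + compose(coeffs, grid)
        p = excitation_psf(w, opt)
        return float((p.intensity**2).sum())

    return metric
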