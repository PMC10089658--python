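"""Direct-AO loop and sensorless modal-sweep tests."""

import numpy as np
import pytest

from retao.dm import build_hex_layout, dm_to_wavefront
from retao.loop import (
    ModalSweepConfig,
    SweepError,
    make_fluorescence_metric,
    run_direct_ao,
    run_modal_system_correction,
)
from retao.psf import OpticalConfig, strehl
from retao.synth import Phantom, VesselConfig, make_vessel_phantom, sample_ocular_aberration
from retao.zernike import PupilGrid, ZernikeCoeffs, compose, remove_modes, rms


@pytest.fixture(scope="module")
def sweep():
    return ModalSweepConfig()


def hidden_metric(mode, amp, grid):
    c = np.zeros(25)
    c[mode - 1] = amp
    return make_fluorescence_metric(compose(ZernikeCoeffs(c), grid))


def test_sweep_grid_construction(sweep):
    assert len(sweep.amplitudes) == 11
    assert len(sweep.mode_set) == 21
    assert sweep.n_evaluations == 231
    assert sweep.amplitudes[0] == pytest.approx(-0.1)
    assert sweep.amplitudes[-1] == pytest.approx(0.1)
    assert 0.0 in np.round(sweep.amplitudes, 12)


def test_sweep_recovers_on_grid_single_mode(small_grid, sweep):
    """A −0.06 µm mode-9 system aberration is recovered exactly."""
    got = run_modal_system_correction(hidden_metric(9, -0.06, small_grid), sweep)
    assert got[9] == pytest.approx(0.06, abs=1e-12)
    assert np.abs(np.delete(got.coeffs, 8)).max() == 0.0


def test_sweep_recovers_off_grid_within_one_step(small_grid, sweep):
    got = run_modal_system_correction(hidden_metric(9, -0.05, small_grid), sweep)
    assert abs(got[9] - 0.05) <= sweep.amp_step_um + 1e-12


def test_sweep_on_perfect_system_selects_all_zeros(small_grid, sweep):
    got = run_modal_system_correction(hidden_metric(9, 0.0, small_grid), sweep)
    assert np.abs(got.coeffs).max() == 0.0


def test_sweep_metric_never_decreases_across_modes(small_grid):
    """Each accepted amplitude can only raise the metric (0 is on the grid)."""
    rng = np.random.default_rng(0)
    c = np.zeros(25)
    c[4:] = 0.04 * rng.standard_normal(21)
    metric = make_fluorescence_metric(compose(ZernikeCoeffs(c), small_grid))
    sweep = ModalSweepConfig()
    history = []
    acc = np.zeros(25)
    for mode in sweep.mode_set:
        got = run_modal_system_correction(
            lambda cf: metric(ZernikeCoeffs(acc[: cf.n_modes] + cf.coeffs)),
            ModalSweepConfig(mode_set=(mode,)),
        )
        acc[: got.n_modes] += got.coeffs
        history.append(metric(ZernikeCoeffs(acc)))
    assert all(b >= a - 1e-9 for a, b in zip(history, history[1:]))


def test_sweep_raises_on_non_finite_metric(sweep):
    with pytest.raises(SweepError):
        run_modal_system_correction(lambda c: np.nan, sweep)


@pytest.fixture(scope="module")
def scene():
    ph = make_vessel_phantom(VesselConfig(size_um=(120, 120, 24), voxel_um=2.0), seed=5)
    return ph


def test_direct_ao_on_perfect_eye_changes_nothing(scene):
    eye = sample_ocular_aberration(5, rms_range_um=(1e-6, 2e-6), fov_um=240.0)
    res = run_direct_ao(scene, eye, grid=PupilGrid(128), opt=OpticalConfig(pad_factor=4))
    assert res.metric_after == pytest.approx(res.metric_before, rel=0.02)
    assert res.metric_after >= res.metric_before  # never applies a worsening DM


def test_direct_ao_restores_strehl_and_reduces_rms(scene):
    """Noiseless single-iteration AO: >5× Strehl, residual < 20% of initial."""
    grid = PupilGrid(128)
    opt = OpticalConfig(pad_factor=4)
    eye = sample_ocular_aberration(6, fov_um=240.0)
    res = run_direct_ao(scene, eye, grid=grid, opt=opt)
    assert res.accepted
    assert res.metric_after > 5 * res.metric_before
    from retao.synth import aberration_at_field

    w0 = remove_modes(aberration_at_field(eye, 0, 0, grid), {1, 2, 3})
    assert res.diagnostics["residual_rms_um"] < 0.2 * rms(w0)


def test_direct_ao_aborts_cleanly_on_dark_area():
    d = np.zeros((5, 40, 40), dtype=np.float32)
    d[2, :5, :5] = 1.0
    ph = Phantom(d, (d > 0).astype(np.uint8), (2.0, 2.0, 2.0))
    eye = sample_ocular_aberration(7, fov_um=160.0)
    res = run_direct_ao(ph, eye, area_center_um=(20.0, 20.0), area_side_um=10.0,
                        grid=PupilGrid(128), opt=OpticalConfig(pad_factor=4))
    assert not res.accepted
    assert "aborted" in res.diagnostics
    assert res.metric_after == res.metric_before


def test_two_stage_correction_composes(scene):
    """System sweep then direct AO on system+eye ends at least as low a
    residual as either stage alone."""
    grid = PupilGrid(128)
    opt = OpticalConfig(pad_factor=4)
    sys_c = np.zeros(25)
    sys_c[8] = -0.06  # system aberration on mode 9
    w_sys = compose(ZernikeCoeffs(sys_c), grid)
    sweep_fix = run_modal_system_correction(
        make_fluorescence_metric(w_sys, opt), ModalSweepConfig()
    )
    w_sys_after = w_sys + compose(sweep_fix, grid)
    eye = sample_ocular_aberration(8, fov_um=240.0)
    # stage residuals, all piston/tip/tilt-free
    from retao.synth import aberration_at_field

    w_eye = aberration_at_field(eye, 0, 0, grid)
    res = run_direct_ao(scene, eye, grid=grid, opt=opt)
    dm_surface = dm_to_wavefront(res.dm_state, grid)
    r_both = rms(remove_modes(w_sys_after + w_eye + dm_surface, {1, 2, 3}))
    r_sweep_only = rms(remove_modes(w_sys_after + w_eye, {1, 2, 3}))
    r_ao_only = rms(remove_modes(w_sys + w_eye + dm_surface, {1, 2, 3}))
    assert r_both <= r_sweep_only + 1e-9
    assert r_both <= r_ao_only + 1e-9


def test_single_iteration_reaches_ninety_percent_reduction():
    """≥90% rms reduction on pure 21-mode aberrations, noiseless sensing."""
    grid = PupilGrid(256)
    reductions = []
    ph = make_vessel_phantom(VesselConfig(size_um=(60, 60, 24), voxel_um=2.0), seed=0)
    for seed in range(5):
        eye = sample_ocular_aberration(seed, field_amp_rel=0.0, fov_um=120.0)
        res = run_direct_ao(ph, eye, grid=grid, area_side_um=19.0)
        w0 = remove_modes(compose(eye.base_coeffs, grid), {1, 2, 3})
        reductions.append(1 - res.diagnostics["residual_rms_um"] / rms(w0))
    assert min(reductions) >= 0.9
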