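"""Synthetic eye, ETL, phantom, and calcium-series generator tests."""

import numpy as np
import pytest
from scipy.ndimage import label as nd_label

from retao.psf import OpticalConfig, strehl
from retao.synth import (
    CalciumProtocol,
    ETLState,
    LesionConfig,
    NeuronConfig,
    Phantom,
    VesselConfig,
    aberration_at_field,
    apply_etl,
    make_calcium_series,
    make_lesion_phantom,
    make_neuron_phantom,
    make_vessel_phantom,
    sample_ocular_aberration,
)
from retao.zernike import PupilGrid, Wavefront, compose, pv, remove_modes, rms


class TestOcularAberrations:
    def test_same_seed_reproduces_coefficients(self):
        a = sample_ocular_aberration(42)
        b = sample_ocular_aberration(42)
        assert np.array_equal(a.base_coeffs.coeffs, b.base_coeffs.coeffs)

    def test_low_modes_untouched(self):
        eye = sample_ocular_aberration(0)
        assert np.all(eye.base_coeffs.coeffs[:4] == 0)

    def test_ensemble_matches_characterized_band(self, grid):
        """Median rms in 0.4-0.8 µm and median P-V ≤ 5 µm over 100 eyes
        (piston/tip/tilt/defocus removed)."""
        rmss, pvs = [], []
        for seed in range(100):
            eye = sample_ocular_aberration(seed)
            w = remove_modes(compose(eye.base_coeffs, grid), {1, 2, 3, 4})
            rmss.append(rms(w))
            pvs.append(pv(w))
        assert 0.4 <= np.median(rmss) <= 0.8
        assert np.median(pvs) <= 5.0

    def test_field_point_is_deterministic(self, small_grid):
        eye = sample_ocular_aberration(5)
        w1 = aberration_at_field(eye, 100.0, -50.0, small_grid)
        w2 = aberration_at_field(eye, 100.0, -50.0, small_grid)
        assert np.array_equal(w1.phase, w2.phase)

    def test_field_difference_grows_with_separation(self, small_grid):
        """Median rms difference at 300 µm exceeds that at 30 µm."""
        near, far = [], []
        for seed in range(50):
            eye = sample_ocular_aberration(seed, fov_um=700.0)
            w0 = aberration_at_field(eye, 0, 0, small_grid)
            near.append(rms(aberration_at_field(eye, 30, 0, small_grid) - w0))
            far.append(rms(aberration_at_field(eye, 300, 0, small_grid) - w0))
        assert np.median(far) > np.median(near)

    def test_zero_perturbation_is_field_invariant(self, small_grid):
        eye = sample_ocular_aberration(3, field_amp_rel=0.0)
        w0 = aberration_at_field(eye, 0, 0, small_grid)
        w1 = aberration_at_field(eye, 250, -250, small_grid)
        assert np.array_equal(w0.phase, w1.phase)

    def test_out_of_fov_raises(self, small_grid):
        eye = sample_ocular_aberration(0, fov_um=100.0)
        with pytest.raises(ValueError):
            aberration_at_field(eye, 60.0, 0.0, small_grid)


class TestETL:
    def test_zero_current_is_identity(self, small_grid):
        w = Wavefront(small_grid, np.zeros((128, 128)))
        out = apply_etl(w, ETLState(current_ma=0.0))
        assert np.array_equal(out.phase, w.phase)

    def test_focal_shift_linear_in_current(self):
        e20 = ETLState(current_ma=20.0)
        e40 = ETLState(current_ma=40.0)
        assert e40.focal_shift_um / e20.focal_shift_um == pytest.approx(2.0, abs=1e-12)

    def test_wavefront_scales_linearly_with_current(self, small_grid):
        w = Wavefront(small_grid, np.zeros((128, 128)))
        w20 = apply_etl(w, ETLState(current_ma=20.0))
        w40 = apply_etl(w, ETLState(current_ma=40.0))
        assert np.allclose(w40.phase, 2 * w20.phase, rtol=1e-12)

    def test_default_parasitic_barely_affects_strehl(self, small_grid):
        """A measured-negligible parasitic term costs < 2% Strehl at 80 mA."""
        w = Wavefront(small_grid, np.zeros((128, 128)))
        etl = ETLState(current_ma=80.0, um_per_ma=0.0, parasitic_per_ma=(0.0, 0.0, 0.0, 0.0, 1e-4, 1e-4))
        out = apply_etl(w, etl)
        assert strehl(out, OpticalConfig(pad_factor=4)) > 0.98


class TestVesselPhantom:
    def test_same_seed_is_bit_identical(self):
        a = make_vessel_phantom(seed=7)
        b = make_vessel_phantom(seed=7)
        assert np.array_equal(a.density, b.density)
        assert np.array_equal(a.labels, b.labels)

    def test_capillary_diameters_within_band(self):
        cfg = VesselConfig()
        for seed in range(20):
            ph = make_vessel_phantom(cfg, seed=seed)
            for diam, kind in ph.meta["segments"]:
                if kind == "capillary":
                    assert cfg.cap_diam_um[0] <= diam <= cfg.cap_diam_um[1]

    def test_density_concentrates_at_plexus_depths(self):
        """The axial density profile has a mode at each configured plexus
        depth, separated by near-empty gaps."""
        cfg = VesselConfig()
        ph = make_vessel_phantom(cfg, seed=1)
        prof = ph.density.sum(axis=(1, 2))
        z_um = np.arange(len(prof)) * cfg.voxel_um
        gaps = np.ones_like(prof, dtype=bool)
        for depth in cfg.plexus_depths_um:
            gaps &= np.abs(z_um - depth) > 10.0
        gap_level = prof[gaps].mean()
        for depth in cfg.plexus_depths_um:
            band = np.abs(z_um - depth) <= 6.0
            assert prof[band].max() > 3 * gap_level

    def test_wall_only_labels_endothelium(self):
        ph = make_vessel_phantom(VesselConfig(wall_only=True), seed=2)
        assert (ph.labels == Phantom.LABEL["wall"]).any()
        assert not (ph.labels == Phantom.LABEL["lumen"]).any()


class TestNeuronPhantom:
    def test_two_soma_layers_in_axial_profile(self):
        cfg = NeuronConfig()
        ph = make_neuron_phantom(cfg, seed=0)
        soma = (ph.labels == Phantom.LABEL["soma"]).sum(axis=(1, 2)).astype(float)
        z_um = np.arange(len(soma)) * cfg.voxel_um
        for depth in cfg.layer_depths_um:
            band = np.abs(z_um - depth) <= cfg.layer_halfwidth_um + 5
            assert soma[band].sum() > 0
        between = (z_um > cfg.layer_depths_um[0] + 10) & (z_um < cfg.layer_depths_um[1] - 10)
        assert soma[between].sum() == 0

    def test_varicosity_count_matches_config(self):
        cfg = NeuronConfig(n_varicosities=12)
        ph = make_neuron_phantom(cfg, seed=3)
        assert ph.meta["n_varicosities"] == 12
        assert (ph.labels == Phantom.LABEL["varicosity"]).any()

    def test_no_soma_centers_in_process_layer(self):
        for seed in range(20):
            cfg = NeuronConfig()
            ph = make_neuron_phantom(cfg, seed=seed)
            lo = cfg.layer_depths_um[0] + cfg.layer_halfwidth_um
            hi = cfg.layer_depths_um[1] - cfg.layer_halfwidth_um
            for zc, _, _ in ph.meta["soma_centers_um"]:
                assert not (lo < zc < hi)


class TestLesionPhantom:
    def test_open_end_face_unlabeled_wall_labeled(self):
        ph = make_lesion_phantom(seed=0)
        x1 = ph.meta["open_face_x_vox"]
        wall = Phantom.LABEL["lesion_wall"]
        assert (ph.labels == wall).any()
        beyond = ph.labels[:, :, x1:]
        assert not (beyond == wall).any()

    def test_cross_section_is_annulus(self):
        """A slice through the stub has a background hole enclosed by wall."""
        ph = make_lesion_phantom(seed=1)
        x1 = ph.meta["open_face_x_vox"]
        sl = ph.labels[:, :, x1 - 5] == Phantom.LABEL["lesion_wall"]
        _, n_bg = nd_label(~sl)
        assert n_bg == 2  # outside + enclosed lumen

    def test_leak_toggle(self):
        on = make_lesion_phantom(LesionConfig(leak=True), seed=2)
        off = make_lesion_phantom(LesionConfig(leak=False), seed=2)
        assert (on.labels == Phantom.LABEL["leak"]).any()
        assert not (off.labels == Phantom.LABEL["leak"]).any()
        wall = off.labels == Phantom.LABEL["lesion_wall"]
        assert off.density[~wall].sum() == 0.0


class TestCalcium:
    def test_total_suppression_floors_the_trace(self):
        """depth=1 gates the spike rate to zero; ΔF/F against the epoch's
        own percentile baseline settles at ≈ 0."""
        from retao.metrics import dff

        cs = make_calcium_series(n_cells=4, protocol=CalciumProtocol(depth=1.0), seed=0)
        sl = cs.protocol.epoch_slices(cs.f.shape[1])
        assert np.all(cs.truth_rate[:, sl["during"]] == 0)
        for f in cs.f:
            d = dff(f, percentile=10.0, window=sl["during"])
            tail = d.dff[sl["during"]][-20:]
            assert np.abs(tail).max() < 5.0  # percent

    def test_suppression_lowers_mean_fluorescence_every_cell(self):
        for seed in range(20):
            cs = make_calcium_series(n_cells=3, seed=seed)
            sl = cs.protocol.epoch_slices(cs.f.shape[1])
            before = cs.f[:, sl["before"]].mean(axis=1)
            during = cs.f[:, sl["during"]].mean(axis=1)
            assert np.all(during < before)

    def test_partial_recovery_sits_between(self):
        cs = make_calcium_series(
            n_cells=6, protocol=CalciumProtocol(depth=0.9, recovery=0.5), seed=1
        )
        sl = cs.protocol.epoch_slices(cs.f.shape[1])
        before = cs.f[:, sl["before"]].mean()
        during = cs.f[:, sl["during"]].mean()
        after = cs.f[:, sl["after"]].mean()
        assert during < after < before

    def test_traces_strictly_positive_and_reproducible(self):
        a = make_calcium_series(n_cells=2, seed=9)
        b = make_calcium_series(n_cells=2, seed=9)
        assert np.all(a.f > 0)
        assert np.array_equal(a.f, b.f)
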