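"""AO/No-AO quantification tests: ratio maps, profiles, spectra, ΔF/F."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from retao.metrics import (
    RatioMap,
    bandwidth_radius,
    dff,
    frequency_map,
    radial_profile,
    ratio_map,
    signal_gain,
)
from retao.synth import CalciumProtocol, make_calcium_series
from retao.zernike import GeometryError


def rand_img(seed=0, n=60):
    return np.random.default_rng(seed).random((n, n)) + 0.5


class TestRatioMap:
    def test_identical_inputs_give_unit_map(self):
        a = rand_img()
        rm = ratio_map(a, a, sigma_px=0)
        assert np.allclose(rm.map, 1.0)

    def test_threefold_input_gives_threefold_map(self):
        a = rand_img(1)
        rm = ratio_map(3 * a, a, sigma_px=0)
        assert np.allclose(rm.map, 3.0)

    def test_scale_covariance(self):
        a, b = rand_img(2), rand_img(3)
        m1 = ratio_map(a, b).map
        mk = ratio_map(5 * a, b).map
        assert np.allclose(mk, 5 * m1)

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            ratio_map(rand_img(0, 60), rand_img(0, 50))

    def test_stacks_are_projected_before_ratio(self):
        rng = np.random.default_rng(4)
        stack = rng.random((5, 30, 30))
        rm = ratio_map(stack, stack, sigma_px=0)
        assert rm.map.shape == (30, 30)
        assert np.allclose(rm.map, 1.0)


class TestRadialProfile:
    def unit_map(self, n=100, px=1.0):
        return RatioMap(np.ones((n, n)), px, 1e-6, 0.0)

    def test_unit_map_profile_is_one_with_max_radius(self):
        prof = radial_profile(self.unit_map())
        assert np.allclose(prof.mean_ratio, 1.0)
        assert prof.effective_radius_um == prof.radii_um[-1]

    def test_cone_map_crosses_unity_at_hundred_microns(self):
        """max(0, 2 − r/100) falls through 1 at r = 100 µm."""
        n = 240
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx + 0.5 - n / 2, yy + 0.5 - n / 2)  # px = 1 µm
        rm = RatioMap(np.maximum(0.0, 2.0 - r / 100.0), 1.0, 1e-6, 0.0)
        prof = radial_profile(rm)
        assert prof.effective_radius_um == pytest.approx(100.0, abs=5.0)

    def test_effective_radius_monotone_in_constant_gain(self):
        n = 240
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx + 0.5 - n / 2, yy + 0.5 - n / 2)
        base = np.maximum(0.0, 1.5 - r / 100.0)
        radii = []
        for gain in (1.0, 1.2, 1.5):
            prof = radial_profile(RatioMap(base * gain, 1.0, 1e-6, 0.0))
            radii.append(prof.effective_radius_um)
        assert radii[0] <= radii[1] <= radii[2]

    def test_single_noise_dip_does_not_end_the_profile(self):
        """One sub-1 bin is noise; two consecutive bins end the radius."""
        n = 200
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx + 0.5 - n / 2, yy + 0.5 - n / 2)
        m = np.where((r >= 30) & (r < 35), 0.9, 1.5)  # one bad 5-µm bin
        prof = radial_profile(RatioMap(m, 1.0, 1e-6, 0.0))
        assert prof.effective_radius_um > 50

    def test_center_outside_map_raises(self):
        with pytest.raises(ValueError):
            radial_profile(self.unit_map(), center_um=(500.0, 0.0))


class TestFrequency:
    def test_delta_image_has_flat_spectrum(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        fm = frequency_map(img)
        assert np.allclose(fm, fm[0, 0], atol=1e-9)

    def test_blur_shrinks_bandwidth(self):
        sharp = rand_img(5, 128)
        blurred = gaussian_filter(sharp, 3.0)
        assert bandwidth_radius(sharp) > bandwidth_radius(blurred)


class TestSignalGain:
    def test_identity_gain_is_one(self):
        a = rand_img(6)
        roi = np.zeros_like(a, dtype=bool)
        roi[20:30, 20:30] = True
        assert signal_gain(a, a, roi) == pytest.approx(1.0)

    def test_fourfold_roi_gain(self):
        # bimodal scene: dim background + bright structure in the ROI
        rng = np.random.default_rng(7)
        a = 0.1 + 0.01 * rng.random((60, 60))
        roi = np.zeros_like(a, dtype=bool)
        roi[10:20, 10:20] = True
        a[roi] = 1.0
        assert signal_gain(4 * a, a, roi) == pytest.approx(4.0, rel=0.02)

    def test_empty_roi_raises(self):
        a = rand_img(8)
        with pytest.raises(ValueError):
            signal_gain(a, a, np.zeros_like(a, dtype=bool))

    def test_degenerate_background_raises(self):
        # No-AO ROI at exactly the background mode level
        a = np.ones((40, 40))
        roi = np.zeros_like(a, dtype=bool)
        roi[5:10, 5:10] = True
        with pytest.raises(ZeroDivisionError):
            signal_gain(a, a, roi)


class TestDff:
    def test_constant_trace_is_zero(self):
        d = dff(np.full(100, 7.0))
        assert np.allclose(d.dff, 0.0)

    def test_percentile_arithmetic(self):
        """Nine samples at 10 and one at 20: F0 = 10, peak ΔF/F = 100%."""
        f = np.array([10.0] * 9 + [20.0])
        d = dff(f, percentile=10.0)
        assert d.f0 == pytest.approx(10.0)
        assert d.dff.max() == pytest.approx(100.0)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_multiplicative_rescaling(self, scale):
        rng = np.random.default_rng(0)
        f = rng.random(200) + 1.0
        base = dff(f).dff
        scaled = dff(scale * f).dff
        assert np.allclose(scaled, base, rtol=1e-9)

    def test_nonpositive_baseline_raises(self):
        f = np.r_[np.zeros(50), np.ones(50)]
        with pytest.raises(ValueError):
            dff(f + 0.0, percentile=10.0)

    def test_suppression_epoch_has_lower_dff_for_every_cell(self):
        """ΔF/F (baseline = treatment epoch, 10th percentile) drops during
        suppression relative to the pre-treatment epoch, 20 seeds."""
        for seed in range(20):
            cs = make_calcium_series(n_cells=3, protocol=CalciumProtocol(), seed=seed)
            sl = cs.protocol.epoch_slices(cs.f.shape[1])
            for f in cs.f:
                d = dff(f, percentile=10.0, window=sl["during"])
                assert d.dff[sl["during"]].mean() < d.dff[sl["before"]].mean()
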