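"""Structure-tensor orientation: gradient conventions, coherency bounds,
the vertical-channels-at-90° convention, and rotation equivariance."""

import numpy as np
import pytest
from skimage.transform import rotate

import scaffoldquant as sq
from scaffoldquant import orientation
from scaffoldquant.orientation import (UntexturedRoiError, compute_gradients,
                                       coherency_weighted_histogram,
                                       structure_tensor_orientation,
                                       summarize_alignment, OrientationField)


def _angular_distance(a, b):
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


class TestGradients:
    def test_constant_image_zero_gradients(self):
        gx, gy = compute_gradients(np.full((16, 16), 9.0))
        assert np.all(gx == 0) and np.all(gy == 0)

    def test_linear_ramp_along_x(self):
        img = np.tile(np.arange(20, dtype=float), (20, 1))
        gx, gy = compute_gradients(img)
        interior = (slice(2, -2), slice(2, -2))
        assert np.allclose(gy[interior], 0)
        assert np.allclose(gx[interior], gx[interior][0, 0])
        assert gx[interior][0, 0] != 0

    def test_transpose_swaps_gradients(self):
        rng = np.random.default_rng(0)
        img = rng.random((24, 24))
        gx, gy = compute_gradients(img)
        gxt, gyt = compute_gradients(img.T)
        assert np.allclose(gxt, gy.T)
        assert np.allclose(gyt, gx.T)

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            compute_gradients(np.zeros((10, 10)), roi=(0, 0, 11, 10))


class TestStructureTensor:
    def test_vertical_stripes_give_90_degrees_coherency_one(self, vertical_stripes):
        gx, gy = compute_gradients(vertical_stripes.astype(float))
        fld = structure_tensor_orientation(gx, gy, window_sigma=2.0)
        textured = fld.coherency > 0
        assert textured.any()
        assert np.allclose(fld.angle_deg[textured], 90.0, atol=1e-6)
        assert np.allclose(fld.coherency[textured], 1.0, atol=1e-9)

    def test_constant_image_zero_coherency(self):
        gx, gy = compute_gradients(np.full((32, 32), 5.0))
        fld = structure_tensor_orientation(gx, gy)
        assert np.all(fld.coherency == 0.0)

    def test_coherency_bounds_on_noise(self):
        rng = np.random.default_rng(1)
        gx, gy = compute_gradients(rng.random((64, 64)) * 255)
        fld = structure_tensor_orientation(gx, gy)
        assert fld.coherency.min() >= 0.0
        assert fld.coherency.max() <= 1.0
        assert np.all(fld.angle_deg >= 0.0) and np.all(fld.angle_deg < 180.0)

    def test_contrast_invariance(self):
        img = sq.gen_channel_field(sq.ChannelFieldSpec(stripe_angle_deg=30.0))
        f1 = structure_tensor_orientation(*compute_gradients(img.astype(float)))
        f2 = structure_tensor_orientation(
            *compute_gradients(img.astype(float) * 3.7))
        assert np.allclose(f1.angle_deg, f2.angle_deg)
        assert np.allclose(f1.coherency, f2.coherency)

    def test_sigma_zero_gives_unit_coherency_where_textured(self):
        img = sq.gen_channel_field(sq.ChannelFieldSpec(stripe_angle_deg=60.0))
        gx, gy = compute_gradients(img.astype(float))
        fld = structure_tensor_orientation(gx, gy, window_sigma=0.0)
        textured = (gx**2 + gy**2) > 1e-9 * float((gx**2 + gy**2).max())
        assert np.allclose(fld.coherency[textured], 1.0)


class TestHistogram:
    def test_single_angle_mass_in_one_bin(self):
        fld = OrientationField(angle_deg=np.full((10, 10), 90.0),
                               coherency=np.ones((10, 10)),
                               roi=(0, 0, 10, 10))
        h = coherency_weighted_histogram(fld, bin_width_deg=1.0)
        assert h.peak_angle_deg == pytest.approx(90.5)
        assert h.peak_density == pytest.approx(1.0)  # all mass in 1 deg bin

    def test_symmetric_two_peak_field(self):
        angles = np.concatenate([np.full(50, 45.0), np.full(50, 135.0)])
        fld = OrientationField(angle_deg=angles.reshape(10, 10),
                               coherency=np.ones((10, 10)), roi=(0, 0, 10, 10))
        h = coherency_weighted_histogram(fld, bin_width_deg=1.0)
        d45 = h.density[45]
        d135 = h.density[135]
        assert d45 == pytest.approx(d135)
        assert d45 == pytest.approx(0.5)

    def test_density_integrates_to_one_on_real_texture(self):
        img = sq.gen_channel_field(
            sq.ChannelFieldSpec(stripe_angle_deg=72.0, noise_sd=10.0, seed=2))
        h = orientation.analyze_image(img)
        widths = np.diff(h.bin_edges)
        assert (h.density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_no_dominant_peak(self):
        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, size=(256, 256)).astype(np.uint8)
        h = orientation.analyze_image(img, bin_width_deg=1.0)
        uniform_level = 1.0 / 180.0
        assert h.peak_density < 3.0 * uniform_level

    def test_bin_width_must_divide_180(self):
        fld = OrientationField(np.full((5, 5), 10.0), np.ones((5, 5)),
                               (0, 0, 5, 5))
        with pytest.raises(ValueError):
            coherency_weighted_histogram(fld, bin_width_deg=7.0)

    def test_untextured_roi_signalled(self):
        fld = OrientationField(np.zeros((5, 5)), np.zeros((5, 5)), (0, 0, 5, 5))
        with pytest.raises(UntexturedRoiError):
            coherency_weighted_histogram(fld)


class TestEquivariance:
    @pytest.mark.parametrize("delta", [15.0, 30.0, 45.0])
    def test_rotation_shifts_peak(self, delta):
        base = 30.0
        img = sq.gen_channel_field(
            sq.ChannelFieldSpec(stripe_angle_deg=base, image_size=(384, 384)))
        rot = rotate(img.astype(float), delta, mode="reflect", order=3)
        # central crop avoids rotation boundary artifacts
        h = orientation.analyze_image(rot, roi=(64, 64, 320, 320))
        assert _angular_distance(h.peak_angle_deg, base + delta) <= 1.0

    @pytest.mark.parametrize("angle", [0.0, 30.0, 90.0, 120.0, 179.0])
    def test_generated_angle_recovered(self, angle):
        img = sq.gen_channel_field(sq.ChannelFieldSpec(stripe_angle_deg=angle))
        h = orientation.analyze_image(img)
        assert _angular_distance(h.peak_angle_deg, angle) <= 1.0


class TestSummarize:
    def _hist(self, peak):
        edges = np.linspace(0, 180, 181)
        dens = np.zeros(180)
        dens[int(peak)] = 1.0
        return orientation.OrientationHistogram(
            bin_edges=edges, density=dens, peak_angle_deg=peak,
            peak_density=1.0, n_pixels=100)

    def test_mean_and_sd_of_peaks(self):
        rep = summarize_alignment([self._hist(p) for p in (89.0, 90.0, 91.0)])
        assert rep["overall"]["mean_peak_deg"] == pytest.approx(90.0)
        assert rep["overall"]["sd_peak_deg"] == pytest.approx(1.0)

    def test_single_histogram_sd_undefined(self):
        rep = summarize_alignment([self._hist(88.0)])
        assert np.isnan(rep["overall"]["sd_peak_deg"])

    def test_grouped_summary(self):
        hists = [self._hist(p) for p in (89.0, 91.0, 70.0, 72.0)]
        rep = summarize_alignment(hists, groups=["top", "top", "bottom",
                                                 "bottom"])
        assert rep["by_group"]["top"]["mean_peak_deg"] == pytest.approx(90.0)
        assert rep["by_group"]["bottom"]["mean_peak_deg"] == pytest.approx(71.0)

    def test_replicate_stripes_mean_near_90(self):
        peaks = []
        for seed in range(5):
            img = sq.gen_channel_field(
                sq.ChannelFieldSpec(stripe_angle_deg=90.0, noise_sd=6.0,
                                    seed=seed))
            peaks.append(orientation.analyze_image(img).peak_angle_deg)
        rep = summarize_alignment([self._hist(p) for p in peaks])
        assert abs(rep["overall"]["mean_peak_deg"] - 90.0) <= 1.0
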