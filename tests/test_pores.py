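"""Pore pipeline: thresholding, labeling (vs a flood-fill oracle),
geometry extraction and distribution construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scaffoldquant as sq
from scaffoldquant import pores
from scaffoldquant.pores import (DegenerateImageError, GrayImage, NoPoresError,
                                 binarize, label_components, pore_distribution,
                                 pore_metrics)

from conftest import flood_fill_label, label_sets


class TestBinarize:
    def test_two_level_image_separates_exactly(self):
        px = np.where(np.eye(8, dtype=bool), 10, 200)
        img = GrayImage(px, 1.0)
        out = binarize(img, polarity="dark_pores")
        assert np.array_equal(out.mask, px == 10)
        assert 10 < out.threshold_used < 200

    def test_bright_polarity_selects_bright_class(self):
        px = np.where(np.eye(8, dtype=bool), 10, 200)
        out = binarize(GrayImage(px, 1.0), polarity="bright_pores")
        assert np.array_equal(out.mask, px == 200)

    def test_constant_image_raises_degenerate(self):
        with pytest.raises(DegenerateImageError):
            binarize(GrayImage(np.full((8, 8), 7), 1.0))

    def test_fixed_threshold_recorded(self):
        px = np.arange(64).reshape(8, 8)
        out = binarize(GrayImage(px, 1.0), method="fixed", fixed_threshold=20)
        assert out.threshold_used == 20
        assert out.mask.sum() == 20

    def test_synthetic_field_mask_matches_ground_truth(self, clean_pore_field):
        spec, img, truth = clean_pore_field
        out = binarize(GrayImage(img, spec.pixel_scale))
        ref = sq.synthetic.rasterize_truth(truth, spec.image_size)
        assert np.array_equal(out.mask, ref)


class TestLabeling:
    def test_single_square(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        lab = label_components(mask, connectivity=8)
        assert lab.max() == 1
        assert (lab == 1).sum() == 25

    def test_diagonal_pixels_connectivity_dependence(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, connectivity=8).max() == 1
        assert label_components(mask, connectivity=4).max() == 2

    def test_synthetic_field_count(self, clean_pore_field):
        spec, img, truth = clean_pore_field
        binary = binarize(GrayImage(img, spec.pixel_scale))
        assert label_components(binary, connectivity=8).max() == len(truth)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(100 + connectivity)
        for _ in range(40):
            shape = rng.integers(2, 33, size=2)
            mask = rng.random(shape) < rng.uniform(0.2, 0.7)
            mine = label_components(mask, connectivity=connectivity)
            oracle = flood_fill_label(mask, connectivity)
            assert mine.max() == oracle.max()
            assert label_sets(mine) == label_sets(oracle)

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, data):
        h = data.draw(st.integers(2, 16))
        w = data.draw(st.integers(2, 16))
        bits = data.draw(st.lists(st.booleans(), min_size=h * w, max_size=h * w))
        mask = np.array(bits, dtype=bool).reshape(h, w)
        conn = data.draw(st.sampled_from([4, 8]))
        mine = label_components(mask, connectivity=conn)
        oracle = flood_fill_label(mask, conn)
        assert label_sets(mine) == label_sets(oracle)

    def test_component_areas_conserve_foreground(self):
        rng = np.random.default_rng(7)
        mask = rng.random((40, 40)) < 0.4
        lab = label_components(mask, connectivity=8)
        assert (lab > 0).sum() == mask.sum()


class TestPoreMetrics:
    def test_rectangle_geometry(self):
        lab = np.zeros((40, 40), int)
        lab[5:25, 10:20] = 1  # 20 tall x 10 wide
        recs, dropped = pore_metrics(lab, pixel_scale=1.0, min_area_px=0)
        assert dropped == 0
        r = recs[0]
        assert r.area_um2 == 200.0
        assert r.aspect_ratio == pytest.approx(0.5)
        assert not r.touches_border

    def test_circle_aspect_ratio_near_one(self):
        yy, xx = np.mgrid[0:101, 0:101]
        lab = (((yy - 50) ** 2 + (xx - 50) ** 2) <= 40**2).astype(int)
        recs, _ = pore_metrics(lab, pixel_scale=1.0)
        assert recs[0].aspect_ratio == pytest.approx(1.0, rel=0.02)

    def test_min_area_filter_reports_drop_count(self):
        lab = np.zeros((10, 10), int)
        lab[1, 1] = 1          # 1 px, dropped
        lab[4:7, 4:7] = 2      # 9 px, kept
        recs, dropped = pore_metrics(lab, pixel_scale=1.0, min_area_px=5)
        assert dropped == 1
        assert [r.label for r in recs] == [2]

    def test_border_touching_flagged(self):
        lab = np.zeros((10, 10), int)
        lab[0:3, 0:3] = 1
        recs, _ = pore_metrics(lab, pixel_scale=1.0)
        assert recs[0].touches_border

    def test_scale_equivariance(self, clean_pore_field):
        spec, img, _ = clean_pore_field
        binary = binarize(GrayImage(img, spec.pixel_scale))
        lab = label_components(binary)
        a, _ = pore_metrics(lab, pixel_scale=2.0, min_area_px=0)
        b, _ = pore_metrics(lab, pixel_scale=6.0, min_area_px=0)
        for ra, rb in zip(a, b):
            assert rb.area_um2 == pytest.approx(ra.area_um2 * 9.0)
            assert rb.aspect_ratio == pytest.approx(ra.aspect_ratio)

    def test_recovery_matches_truth_areas_and_aspect(self, clean_pore_field):
        spec, img, truth = clean_pore_field
        res = pores.analyze_image(GrayImage(img, spec.pixel_scale),
                                  min_area_px=0)
        assert res["pore_count"] == len(truth)
        got = res["table"].sort_values(["area_um2", "aspect_ratio"])
        want = truth.sort_values(["area_raster_um2", "bbox_aspect"])
        np.testing.assert_allclose(got["area_um2"].to_numpy(),
                                   want["area_raster_um2"].to_numpy())
        np.testing.assert_allclose(got["aspect_ratio"].to_numpy(),
                                   want["bbox_aspect"].to_numpy())


class TestPoreDistribution:
    def _records(self, values):
        return [pores.PoreRecord(label=i + 1, area_um2=v, bbox_width_um=1.0,
                                 bbox_height_um=1.0, aspect_ratio=v,
                                 touches_border=False)
                for i, v in enumerate(values)]

    def test_single_record_density_integrates_to_one(self):
        dist = pore_distribution(self._records([5.0]), "area", n_bins=10)
        widths = np.diff(dist.bin_edges)
        assert (dist.densities * widths).sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("binning", ["linear", "log"])
    def test_density_normalization_on_samples(self, binning):
        rng = np.random.default_rng(2)
        recs = self._records(rng.lognormal(3, 1, 500))
        dist = pore_distribution(recs, "area", binning=binning, n_bins=25)
        widths = np.diff(dist.bin_edges)
        assert (dist.densities * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_lognormal_refit_recovers_parameters(self):
        rng = np.random.default_rng(4)
        mu, sigma, n = 6.0, 0.5, 10_000
        recs = self._records(rng.lognormal(mu, sigma, n))
        dist = pore_distribution(recs, "area", binning="log", n_bins=40)
        logs = np.log([r.area_um2 for r in recs])
        assert abs(logs.mean() - mu) < 3 * sigma / np.sqrt(n)
        assert dist.n == n

    def test_equal_values_have_zero_iqr(self):
        dist = pore_distribution(self._records([2.0] * 9), "aspect_ratio")
        assert dist.boxplot["q3"] - dist.boxplot["q1"] == 0.0

    def test_empty_records_signal_no_pores(self):
        with pytest.raises(NoPoresError):
            pore_distribution([], "area")
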