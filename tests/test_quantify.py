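"""ROI determination and tile measurement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.morphology import dilation, disk

import precisionif as pf
from conftest import otsu_bruteforce


def _tile(dapi, ck, her2, tile_id=(0, 0)):
    return pf.TileImage(dapi=dapi, ck=ck, her2=her2, tile_id=tile_id)


class TestAutoThreshold:
    def test_bimodal_image_threshold_separates_modes(self):
        img = np.full((32, 32), 0.1)
        img[:16] = 0.9
        t = pf.auto_threshold(img)
        assert 0.1 < t < 0.9

    def test_constant_image_returns_the_constant(self):
        assert pf.auto_threshold(np.full((8, 8), 0.3)) == pytest.approx(0.3)

    def test_matches_bruteforce_between_class_variance_search(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            img = np.clip(rng.normal(0.3, 0.1, (48, 48)), 0, 1)
            img[:16] = np.clip(rng.normal(0.7, 0.08, (16, 48)), 0, 1)
            # ties on a variance plateau are allowed: compare the partitions
            np.testing.assert_array_equal(
                img > pf.auto_threshold(img), img > otsu_bruteforce(img))

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            pf.auto_threshold(np.array([]))
        with pytest.raises(ValueError):
            pf.auto_threshold(np.array([[0.1, np.nan], [0.2, 0.3]]))


class TestComputeRoi:
    def test_tile_without_nuclei_roi_equals_ck_foreground(self):
        rng = np.random.default_rng(1)
        ck = np.clip(0.05 + rng.normal(0, 0.01, (64, 64)), 0, 1)
        ck[16:48, 16:48] = 0.55
        dapi = np.clip(0.05 + rng.normal(0, 0.01, (64, 64)), 0, 1)
        tile = _tile(dapi, ck, ck * 0.5)
        roi = pf.compute_roi(tile)
        np.testing.assert_array_equal(roi.mask, ck >= roi.ck_threshold)

    def test_nuclei_covering_all_epithelium_empty_roi(self):
        ck = np.full((32, 32), 0.05)
        ck[8:24, 8:24] = 0.6
        dapi = np.full((32, 32), 0.05)
        dapi[6:26, 6:26] = 0.9  # nuclear mask blankets the CK foreground
        roi = pf.compute_roi(_tile(dapi, ck, ck))
        assert roi.roi_area == 0

    def test_stroma_only_tile_has_empty_roi(self):
        rng = np.random.default_rng(2)
        noise = lambda: np.clip(0.05 + rng.normal(0, 0.01, (64, 64)), 0, 1)
        roi = pf.compute_roi(_tile(noise(), noise(), noise()))
        assert roi.roi_area == 0

    def test_roi_matches_generator_ground_truth(self):
        ph = pf.CasePhenotype(expression_level=0.3, epithelial_fraction=1.0,
                              n_tiles=5, seed=3)
        tiles, truths = pf.generate_case_with_truth(ph)
        config = pf.QuantConfig()
        for tile, truth in zip(tiles, truths):
            roi = pf.compute_roi(tile, config)
            expected = truth.epithelium & ~dilation(
                truth.nuclei, disk(config.dilation_radius))
            inter = (roi.mask & expected).sum()
            union = (roi.mask | expected).sum()
            assert inter / union >= 0.8

    def test_roi_never_below_ck_threshold_nor_in_dilated_nuclei(self):
        ph = pf.CasePhenotype(expression_level=0.4, n_tiles=8, seed=4)
        config = pf.QuantConfig()
        for tile in pf.generate_case(ph):
            roi = pf.compute_roi(tile, config)
            if roi.roi_area == 0:
                continue
            assert tile.ck[roi.mask].min() >= roi.ck_threshold
            dapi_fg = tile.dapi >= roi.dapi_threshold
            contrast = tile.dapi[dapi_fg].mean() - tile.dapi[~dapi_fg].mean()
            if contrast >= config.noise_floor:  # nuclear exclusion active
                nuclei = dilation(dapi_fg, disk(config.dilation_radius))
                assert not np.any(roi.mask & nuclei)


class TestMeasureTile:
    def test_arithmetic_mean_over_roi(self):
        ck = np.full((4, 4), 0.5)
        her2 = np.zeros((4, 4))
        her2[0, :2] = 0.2
        her2[0, 2:] = 0.4
        mask = np.zeros((4, 4), dtype=bool)
        mask[0] = True
        roi = pf.RoiMask(mask=mask, ck_threshold=0.1, dapi_threshold=0.1)
        m = pf.measure_tile(_tile(np.zeros((4, 4)), ck, her2), roi,
                            pf.QuantConfig(min_roi_pixels=2))
        assert m.her2_mean == pytest.approx(0.3)
        assert m.ck_mean == pytest.approx(0.5)
        assert m.valid

    def test_empty_roi_invalid_with_nan_means(self):
        roi = pf.RoiMask(mask=np.zeros((4, 4), dtype=bool),
                         ck_threshold=0.1, dapi_threshold=0.1)
        m = pf.measure_tile(_tile(*(np.full((4, 4), 0.2),) * 3), roi)
        assert not m.valid
        assert np.isnan(m.ck_mean) and np.isnan(m.her2_mean)

    def test_shape_mismatch_rejected(self):
        roi = pf.RoiMask(mask=np.ones((3, 3), dtype=bool),
                         ck_threshold=0.1, dapi_threshold=0.1)
        with pytest.raises(ValueError):
            pf.measure_tile(_tile(*(np.full((4, 4), 0.2),) * 3), roi)

    @given(st.integers(0, 2**31 - 1))
    def test_means_invariant_to_pixel_permutation(self, seed):
        rng = np.random.default_rng(seed)
        ck = rng.random((8, 8))
        her2 = rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.4
        if not mask.any():
            mask[0, 0] = True
        roi = pf.RoiMask(mask=mask, ck_threshold=0.0, dapi_threshold=0.0)
        m = pf.measure_tile(_tile(np.zeros((8, 8)), ck, her2), roi,
                            pf.QuantConfig(min_roi_pixels=1))
        perm = rng.permutation(64)
        ck_p = ck.ravel()[perm].reshape(8, 8)
        her2_p = her2.ravel()[perm].reshape(8, 8)
        mask_p = mask.ravel()[perm].reshape(8, 8)
        roi_p = pf.RoiMask(mask=mask_p, ck_threshold=0.0, dapi_threshold=0.0)
        m_p = pf.measure_tile(_tile(np.zeros((8, 8)), ck_p, her2_p), roi_p,
                              pf.QuantConfig(min_roi_pixels=1))
        assert m_p.ck_mean == pytest.approx(m.ck_mean)
        assert m_p.her2_mean == pytest.approx(m.her2_mean)


class TestMeasureCase:
    def test_order_preserved_and_invalid_counted(self):
        ph = pf.CasePhenotype(expression_level=0.3, epithelial_fraction=0.6,
                              n_tiles=20, seed=6)
        tiles = pf.generate_case(ph)
        ms = pf.measure_case(tiles)
        assert [m.tile_id for m in ms] == [t.tile_id for t in tiles]
        assert any(not m.valid for m in ms)  # stromal tiles measure nothing
        assert any(m.valid for m in ms)

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError):
            pf.measure_case([])

    def test_zero_noise_ck_mean_is_exact(self):
        """Without pixel noise the ROI CK mean equals the configured level."""
        model = pf.ImagingModel(noise_sd=0.0)
        ph = pf.CasePhenotype(expression_level=0.3, epithelial_fraction=1.0,
                              n_tiles=5, seed=8)
        for m in pf.measure_case(pf.generate_case(ph, model)):
            if m.valid:
                assert m.ck_mean == pytest.approx(
                    model.background_ck + model.ck_level)

    def test_expression_doubling_roughly_doubles_her2(self):
        model = pf.ImagingModel(background_her2=0.0, noise_sd=0.005)
        means = []
        for level in (0.2, 0.4):
            ph = pf.CasePhenotype(expression_level=level, epithelial_fraction=1.0,
                                  n_tiles=30, seed=10)
            ms = [m for m in pf.measure_case(pf.generate_case(ph, model)) if m.valid]
            means.append(np.mean([m.her2_mean for m in ms]))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.1)


class TestTileImageValidation:
    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            _tile(np.zeros((4, 4)), np.zeros((4, 5)), np.zeros((4, 4)))

    def test_out_of_range_intensities_rejected(self):
        with pytest.raises(ValueError):
            _tile(np.zeros((4, 4)), np.full((4, 4), 1.5), np.zeros((4, 4)))
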