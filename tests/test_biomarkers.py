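"""Angiography analytics: en-face maps, regional means, group testing and the
dice evaluator."""

import numpy as np
import pytest

from chorangio.biomarkers import (
    EnFaceMap,
    cvi_maps,
    dice_eval,
    enface_density,
    group_compare,
    region_mean,
    region_table,
    segment_cube,
    thickness_maps,
)
from chorangio.data import combine_labels
from chorangio.phantom import generate_cube

from conftest import small_params


def _emap(values, fovea=None, spacing=0.05):
    fovea = fovea or (values.shape[0] // 2, values.shape[1] // 2)
    return EnFaceMap(values.astype(np.float32), "CVI", spacing, spacing, fovea)


class TestEnFaceDensity:
    def test_background_volume_is_zero(self):
        out = enface_density(np.zeros((3, 10, 4), np.uint8))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_column_fraction_counts(self):
        vol = np.zeros((1, 100, 1), np.uint8)
        vol[0, :10, 0] = 1
        assert enface_density(vol).values[0, 0] == pytest.approx(0.10)

    def test_values_in_unit_interval(self, rng):
        vol = rng.integers(0, 3, (4, 12, 6)).astype(np.uint8)
        out = enface_density(vol).values
        assert out.min() >= 0 and out.max() <= 1


class TestCVIMaps:
    def test_cvi_h_direct_count(self):
        sub = np.zeros((1, 100, 1), np.uint8)
        sub[0, 10:50, 0] = 2  # 40 px of HL
        labels = np.zeros((1, 100, 1), np.uint8)
        labels[0, 10:30, 0] = 2  # 20 px of HV
        _, cvi_h, _ = cvi_maps(labels, sub)
        assert cvi_h.values[0, 0] == pytest.approx(0.5)

    def test_no_vessels_gives_zero_where_layers_exist(self):
        sub = np.ones((2, 20, 3), np.uint8)
        cvi, cvi_h, cvi_s = cvi_maps(np.zeros_like(sub), sub)
        np.testing.assert_array_equal(cvi.values, 0.0)
        assert np.isnan(cvi_h.values).all()  # no HL anywhere -> missing
        np.testing.assert_array_equal(cvi_s.values, 0.0)

    def test_missing_columns_are_nan_not_zero(self):
        sub = np.zeros((1, 10, 2), np.uint8)
        sub[0, :, 0] = 2
        labels = np.zeros_like(sub)
        _, cvi_h, _ = cvi_maps(labels, sub)
        assert cvi_h.values[0, 0] == 0.0 and np.isnan(cvi_h.values[0, 1])

    def test_phantom_cube_recovers_planted_hl_fraction(self):
        # full-size cube, macular 12-mm region: enough tubes for the regional
        # mean to estimate the planted volume fraction tightly
        from chorangio.phantom import PhantomParams

        cube = generate_cube(PhantomParams(), seed=21)
        labels = combine_labels(cube.vessel_volume(), cube.sublayer_volume())
        _, cvi_h, _ = cvi_maps(labels, cube.sublayer_volume(),
                               fovea_center=cube.fovea_center,
                               slice_spacing_mm=cube.slice_spacing,
                               lateral_spacing_mm=cube.lateral_spacing)
        recovered = region_mean(cvi_h, 12.0)
        planted = cube.slices[0].params.vessel_density_hl
        assert recovered == pytest.approx(planted, abs=0.03)

    def test_cvi_bounded_by_sublayer_cvis(self, rng):
        sub = rng.integers(0, 3, (3, 30, 5)).astype(np.uint8)
        vessel = (rng.random((3, 30, 5)) < 0.4).astype(np.uint8)
        labels = combine_labels(vessel, sub)
        cvi, cvi_h, cvi_s = cvi_maps(labels, sub)
        ok = np.isfinite(cvi_h.values) & np.isfinite(cvi_s.values)
        lo = np.minimum(cvi_h.values[ok], cvi_s.values[ok])
        hi = np.maximum(cvi_h.values[ok], cvi_s.values[ok])
        assert (cvi.values[ok] >= lo - 1e-6).all()
        assert (cvi.values[ok] <= hi + 1e-6).all()


class TestThickness:
    def test_pixel_count_times_spacing(self):
        sub = np.zeros((1, 100, 1), np.uint8)
        sub[0, :50, 0] = 2
        ct_h, ct_s = thickness_maps(sub, 3.9)
        assert ct_h.values[0, 0] == pytest.approx(195.0)
        assert ct_s.values[0, 0] == 0.0

    def test_independent_of_vessel_content(self, rng):
        sub = rng.integers(0, 3, (2, 20, 4)).astype(np.uint8)
        ct1 = thickness_maps(sub, 3.9)[0].values
        ct2 = thickness_maps(sub.copy(), 3.9)[0].values
        np.testing.assert_array_equal(ct1, ct2)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            thickness_maps(np.zeros((1, 2, 2), np.uint8), 0.0)


class TestRegionMean:
    def test_constant_map(self):
        emap = _emap(np.full((64, 64), 0.37))
        for d in (1, 2, 3):
            assert region_mean(emap, d) == pytest.approx(0.37)

    def test_planted_disk_area_ratio(self):
        # value 1 inside a 3-mm-diameter disk; 6-mm region mean = 0.25
        n = 256
        spacing = 0.05
        center = (n // 2, n // 2)
        t = (np.arange(n) - center[0]) * spacing
        x = (np.arange(n) - center[1]) * spacing
        disk = (t[:, None] ** 2 + x[None, :] ** 2) <= 1.5 ** 2
        emap = _emap(disk.astype(np.float32), fovea=center, spacing=spacing)
        assert region_mean(emap, 1.0) == pytest.approx(1.0)
        assert region_mean(emap, 6.0) == pytest.approx(0.25, abs=0.02)

    def test_radius_unit_doubles_the_region(self):
        emap = _emap(np.ones((64, 64)))
        assert region_mean(emap, 1.0, unit="radius") == pytest.approx(1.0)

    def test_missing_pixels_excluded(self):
        vals = np.full((64, 64), 0.4, np.float32)
        vals[:32] = np.nan
        assert region_mean(_emap(vals), 2.0) == pytest.approx(0.4)

    def test_region_outside_map_rejected(self):
        emap = _emap(np.ones((8, 8)), fovea=(400, 400))
        with pytest.raises(ValueError):
            region_mean(emap, 1.0)

    def test_region_table_collects_all_quantities(self):
        emap = _emap(np.full((32, 32), 0.5))
        df = region_table([{"subject": "s1", "group": "healthy",
                            "maps": {"CVI": emap}}], diameters_mm=(1, 2))
        assert list(df["region_mm"]) == [1, 2]
        assert df["CVI"].tolist() == pytest.approx([0.5, 0.5])


class TestGroupCompare:
    def test_identical_groups_give_t_zero_p_one(self):
        g = [0.4, 0.5, 0.6]
        res = group_compare(g, g)
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0.48, 0.03, 50)
        g2 = rng.normal(0.44, 0.03, 20)
        res = group_compare(g1, g2)
        assert res["p"] < 1e-3 and res["t"] > 0

    def test_welch_matches_textbook_formula_on_small_example(self):
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([2.0, 4.0, 9.0])
        res = group_compare(g1, g2)
        se = np.sqrt(g1.var(ddof=1) / 3 + g2.var(ddof=1) / 3)
        assert res["t"] == pytest.approx((g1.mean() - g2.mean()) / se)

    def test_paired_mode_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], [1, 2], paired=True)
        res = group_compare([1.0, 2.0, 3.0], [1.5, 2.5, 3.6], paired=True)
        assert res["paired"] and res["p"] < 0.05

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [1.0, 2.0])


class TestDiceEval:
    def test_perfect_prediction_scores_100_everywhere(self, rng):
        sub = rng.integers(0, 3, (2, 10, 8)).astype(np.uint8)
        vessel = (rng.random((2, 10, 8)) < 0.3).astype(np.uint8)
        scores = dice_eval(vessel, sub, vessel, sub)
        assert all(v == pytest.approx(100.0) for v in scores.values())

    def test_disjoint_nonempty_sets_score_zero(self):
        a = np.zeros((4, 4), np.uint8)
        a[:2] = 1
        b = np.zeros((4, 4), np.uint8)
        b[2:] = 1
        sub = np.ones((4, 4), np.uint8)
        assert dice_eval(a, sub, b, sub)["CV"] == 0.0

    def test_random_masks_match_set_arithmetic_oracle(self, rng):
        pv = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        gv = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        pl = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        gl = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        scores = dice_eval(pv, pl, gv, gl)
        inter = ((pl == 1) & (gl == 1)).sum()
        expected = 200 * inter / ((pl == 1).sum() + (gl == 1).sum())
        assert scores["SL"] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_eval(np.zeros((2, 2), np.uint8), np.zeros((2, 2), np.uint8),
                      np.zeros((3, 3), np.uint8), np.zeros((3, 3), np.uint8))


class TestSegmentCube:
    def test_oracle_probabilities_reproduce_combined_labels(self):
        cube = generate_cube(small_params(slice_count=6), seed=9)
        gt_vessel = cube.vessel_volume()
        gt_sub = cube.sublayer_volume()
        counter = iter(range(len(cube.slices)))

        def oracle(img):
            i = next(counter)  # segment_cube visits slices in order
            layer = np.zeros((3,) + img.shape, np.float32)
            vessel = np.zeros((2,) + img.shape, np.float32)
            for c in range(3):
                layer[c][gt_sub[i] == c] = 1
            vessel[1][gt_vessel[i] == 1] = 1
            vessel[0] = 1 - vessel[1]
            return layer, vessel

        labels, sublayers = segment_cube(cube.image_volume(), oracle)
        np.testing.assert_array_equal(labels, combine_labels(gt_vessel, gt_sub))
        np.testing.assert_array_equal(sublayers, gt_sub)
        scores = dice_eval(labels > 0, sublayers, gt_vessel, gt_sub)
        assert all(v == pytest.approx(100.0) for v in scores.values())

    def test_slice_count_preserved_and_deterministic(self):
        cube = generate_cube(small_params(slice_count=4), seed=2)
        const_layer = np.zeros((3, 48, 64), np.float32)
        const_layer[0] = 1
        const_vessel = np.zeros((2, 48, 64), np.float32)
        const_vessel[0] = 1
        predictor = lambda img: (const_layer, const_vessel)
        l1, s1 = segment_cube(cube.image_volume(), predictor)
        l2, s2 = segment_cube(cube.image_volume(), predictor)
        assert l1.shape[0] == 4
        np.testing.assert_array_equal(l1, l2)
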