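"""Concentric ROIs, penetrability, morphometry and circularity phenotyping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecs_rheomap import plaque
from ecs_rheomap.simkit import _disk_mask


class TestCircleApproximation:
    def test_area_pi_gives_unit_radius(self):
        assert plaque.area_to_radius(math.pi) == pytest.approx(1.0)

    def test_cortical_median_area_gives_5_1_um(self):
        assert plaque.area_to_radius(81.71) == pytest.approx(5.10, abs=0.005)

    def test_zero_area_zero_radius(self):
        assert plaque.area_to_radius(0.0) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            plaque.area_to_radius(-1.0)

    def test_ring_width_unit_case(self):
        # core r=1 (A=pi), total r=2 (A=4pi) -> width 1
        assert plaque.ring_width(math.pi, 3 * math.pi) == pytest.approx(1.0)

    def test_zero_ring_area_zero_width(self):
        assert plaque.ring_width(2.0, 0.0) == 0.0

    def test_width_radius_ratio_implies_area_ratio(self):
        """w/r = 1.82 is equivalent to A_ring/A_core = (1+1.82)² - 1."""
        r = 5.1
        a_core = math.pi * r ** 2
        a_ring = a_core * ((1 + 1.82) ** 2 - 1)
        w = plaque.ring_width(a_core, a_ring)
        assert w / r == pytest.approx(1.82, rel=1e-9)
        assert a_ring / a_core == pytest.approx(6.9524, abs=1e-4)

    def test_volume_ratio_is_exact_cube(self):
        a_core = math.pi * 5.1 ** 2
        a_ring = a_core * ((1 + 1.82) ** 2 - 1)
        assert plaque.volume_ratio(a_core, a_ring) == pytest.approx(2.82 ** 3)


class TestConcentricRois:
    def test_core_radius_5_gives_ring_outer_14_1(self):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 5.0))
        assert roi.ring_outer_radius == pytest.approx(14.1)
        assert roi.out_outer_radius == pytest.approx(28.2)

    def test_zero_ring_factor_rejected(self):
        with pytest.raises(ValueError):
            plaque.build_concentric_rois(((0.0, 0.0), 5.0), ring_factor=0.0)

    def test_mask_core_matches_parametric(self):
        px = 0.1
        mask = _disk_mask(400, 50.0, (200.0, 200.0))  # r = 5 µm at 0.1 µm/px
        roi_m = plaque.build_concentric_rois(mask, pixel_size=px)
        roi_p = plaque.build_concentric_rois(((20.0, 20.0), 5.0))
        assert roi_m.core_radius == pytest.approx(roi_p.core_radius, abs=px)
        assert roi_m.center[0] == pytest.approx(20.0, abs=px)
        assert roi_m.ring_outer_radius == pytest.approx(roi_p.ring_outer_radius,
                                                        abs=3 * px)

    def test_clipping_flagged(self):
        with pytest.warns(UserWarning, match="clipped"):
            roi = plaque.build_concentric_rois(((10.0, 10.0), 3.0),
                                               field_um=(20.0, 20.0))
        assert roi.clipped

    def test_region_areas_are_additive(self):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 2.0))
        areas = roi.areas()
        total = math.pi * roi.out_outer_radius ** 2
        assert sum(areas.values()) == pytest.approx(total, rel=1e-12)

    def test_boundary_point_assigned_to_inner_region(self):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 2.0))
        labels = roi.label_points([(2.0, 0.0), (roi.ring_outer_radius, 0.0)])
        assert list(labels) == ["Amyloid", "Ring"]


class TestDensityAndPenetrability:
    def test_no_points_zero_densities(self):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 2.0))
        d = plaque.localization_density(np.empty((0, 2)), roi)
        assert (d["density_per_um2"] == 0).all()

    def test_points_only_in_core(self):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 2.0))
        pts = np.random.default_rng(0).uniform(-1, 1, (50, 2)) * 0.5
        d = plaque.localization_density(pts, roi).set_index("region")
        assert d.loc["Out", "n_locs"] == 0 and d.loc["Ring", "n_locs"] == 0
        assert d.loc["Amyloid", "n_locs"] == 50

    def test_uniform_points_give_equal_densities_within_3se(self, rng):
        roi = plaque.build_concentric_rois(((0.0, 0.0), 5.0))
        L = roi.out_outer_radius
        pts = rng.uniform(-L, L, (20_000, 2))
        d = plaque.localization_density(pts, roi).set_index("region")
        intensity = 20_000 / (2 * L) ** 2
        for region in ("Amyloid", "Ring", "Out"):
            n = d.loc[region, "n_locs"]
            area = d.loc[region, "area_um2"]
            se = math.sqrt(intensity * area) / area
            assert abs(d.loc[region, "density_per_um2"] - intensity) < 3 * se

    def test_equal_densities_ratio_one(self):
        import pandas as pd
        dens = pd.DataFrame({"region": ["Amyloid", "Ring", "Out"],
                             "n_locs": [1, 1, 1],
                             "area_um2": [1.0, 1.0, 1.0],
                             "density_per_um2": [2.0, 2.0, 2.0]})
        assert plaque.penetrability_ratio(dens, "Out/Ring") == 1.0
        assert plaque.penetrability_ratio(dens, "Ring/Amyloid") == 1.0

    def test_double_outer_density_ratio_two(self):
        import pandas as pd
        dens = pd.DataFrame({"region": ["Ring", "Out"], "n_locs": [1, 2],
                             "area_um2": [1.0, 1.0],
                             "density_per_um2": [1.0, 2.0]})
        assert plaque.penetrability_ratio(dens, "Out/Ring") == 2.0

    def test_zero_inner_density_missing(self):
        import pandas as pd
        dens = pd.DataFrame({"region": ["Ring", "Out"], "n_locs": [0, 2],
                             "area_um2": [1.0, 1.0],
                             "density_per_um2": [0.0, 2.0]})
        assert math.isnan(plaque.penetrability_ratio(dens, "Out/Ring"))


class TestProjectionThresholdWand:
    def test_max_projection_of_identical_slices(self, rng):
        img = rng.uniform(size=(16, 16))
        stack = np.stack([img] * 10)
        np.testing.assert_array_equal(plaque.max_projection(stack), img)

    def test_max_projection_unions_disjoint_spots(self):
        a = np.zeros((8, 8)); a[2, 2] = 5.0
        b = np.zeros((8, 8)); b[6, 6] = 3.0
        proj = plaque.max_projection(np.stack([a, b]))
        assert proj[2, 2] == 5.0 and proj[6, 6] == 3.0

    def test_isodata_two_level_fixed_point(self):
        img = np.array([10.0] * 60 + [200.0] * 40)
        assert plaque.isodata_threshold(img) == pytest.approx(105.0)

    def test_isodata_shift_invariance(self, rng):
        img = rng.normal(50, 5, 500)
        img[::3] += 100
        t0 = plaque.isodata_threshold(img)
        t1 = plaque.isodata_threshold(img + 37.0)
        assert t1 == pytest.approx(t0 + 37.0, abs=1e-6)

    def test_isodata_separates_well_split_modes(self, rng):
        lo = rng.normal(20, 2, 5000)
        hi = rng.normal(80, 2, 5000)
        t = plaque.isodata_threshold(np.concatenate([lo, hi]))
        miscls = np.mean(lo > t) + np.mean(hi <= t)
        assert miscls < 0.05

    def test_isodata_constant_image_rejected(self):
        with pytest.raises(ValueError):
            plaque.isodata_threshold(np.full((4, 4), 3.0))

    def test_wand_selects_only_seeded_blob(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[7:9, 7:9] = True
        comp = plaque.wand_select(mask, (1, 1))
        assert comp[1, 1] and not comp[7, 7]
        assert comp.sum() == 4

    def test_wand_uses_8_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True   # diagonal touch
        comp = plaque.wand_select(mask, (1, 1))
        assert comp.sum() == 2

    def test_wand_background_seed_rejected(self):
        with pytest.raises(ValueError):
            plaque.wand_select(np.zeros((3, 3), bool), (0, 0))


class TestCircularity:
    def test_disk_is_compact(self):
        c = plaque.circularity(_disk_mask(128, 50.0))
        assert c > 0.28
        assert c == pytest.approx(0.9, abs=0.1)

    def test_thin_bar_is_filamentous(self):
        mask = np.zeros((5, 210), bool)
        mask[2, 5:205] = True
        c = plaque.circularity(mask)
        assert c <= 0.14
        assert c == pytest.approx(4 * math.pi * 200 / 402 ** 2, rel=0.05)

    def test_single_pixel_unit_square_convention(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert plaque.circularity(mask) == pytest.approx(4 * math.pi / 16)

    def test_invariant_under_translation_and_rotation(self):
        base = _disk_mask(64, 20.0, (30.0, 28.0))
        c0 = plaque.circularity(base)
        assert plaque.circularity(np.roll(base, (3, -2), axis=(0, 1))) == pytest.approx(c0)
        assert plaque.circularity(np.rot90(base)) == pytest.approx(c0)

    def test_disk_circularity_converges_with_radius(self):
        """Discretization error decreases with radius; the traced-polygon
        estimator converges to a constant slightly below the continuous
        isoperimetric limit of 1 (the contour polygon overestimates a smooth
        perimeter by a few percent)."""
        cs = [plaque.circularity(_disk_mask(8 * r, float(r))) for r in (10, 40, 120)]
        assert abs(cs[2] - cs[1]) < abs(cs[1] - cs[0])
        assert cs[2] == pytest.approx(0.9, abs=0.05)

    @pytest.mark.parametrize("c,expected", [
        (0.10, "filamentous"), (0.14, "filamentous"),
        (0.1401, "intermediate"), (0.20, "intermediate"), (0.28, "intermediate"),
        (0.2801, "compact"), (0.29, "compact"), (1.0, "compact"),
    ])
    def test_phenotype_classes(self, c, expected):
        assert plaque.classify_phenotype(c) == expected

    @given(st.floats(min_value=0, max_value=2, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_classification_total_and_monotone(self, c):
        order = ["filamentous", "intermediate", "compact"]
        assert plaque.classify_phenotype(c) in order
        # monotone: higher circularity never moves to an earlier class
        assert (order.index(plaque.classify_phenotype(min(c + 0.1, 2.1)))
                >= order.index(plaque.classify_phenotype(c)))


class TestLognormality:
    def test_lognormal_sample_passes(self, rng):
        areas = 134.2 * np.exp(rng.normal(0, 0.8, 10_000))
        passed, _, p = plaque.lognormality_check(areas)
        assert passed and p > 0.05

    def test_uniform_sample_fails_at_large_n(self, rng):
        areas = rng.uniform(1, 100, 10_000)
        passed, _, _ = plaque.lognormality_check(areas)
        assert not passed

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            plaque.lognormality_check([1.0] * 7)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            plaque.lognormality_check([1.0] * 9 + [0.0])
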