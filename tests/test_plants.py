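"""Digital-plant construction and morpho-colorimetric features."""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenoplate import plants
from phenoplate.imgproc import Component, label_components
from phenoplate.plants import (
    DigitalPlant,
    ObjectFilterSpec,
    PlateLayout,
    compute_morphology,
    contour_perimeter,
    filter_objects,
    hue_class_histogram,
    merge_shoot_root,
    select_largest_per_cell,
    trace_outer_contour,
    yellow_damage_fraction,
)


def _component(mask: np.ndarray, label=1, offset=(0, 0)) -> Component:
    rr, cc = np.nonzero(mask)
    return Component(
        label=label,
        mask=mask,
        offset=offset,
        area=int(mask.sum()),
        centroid=(float(cc.mean() + offset[1]), float(rr.mean() + offset[0])),
    )


def _plant(mask, offset=(0, 0)) -> DigitalPlant:
    c = _component(mask, offset=offset)
    return DigitalPlant.from_component(c, line_id="L")


def _disk(radius, pad=3):
    r = radius + pad
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx**2 + yy**2 <= radius**2


def _hsb_raster(shape, hue, sat=200, bri=200):
    out = np.zeros(shape + (3,), dtype=np.uint8)
    out[..., 0] = hue
    out[..., 1] = sat
    out[..., 2] = bri
    return out


class TestMorphology:
    def test_rectangle_perimeter_area_compactness(self):
        mask = np.zeros((16, 26), bool)
        mask[3:13, 3:23] = True  # 20 x 10
        prof = compute_morphology(_plant(mask), np.full((16, 26), 100, np.uint8))
        assert prof.area == 200
        assert prof.perimeter == pytest.approx(56.0)
        assert prof.compactness == pytest.approx(200 / 56, rel=1e-6)
        assert prof.hisgreypeak == 100

    def test_disk_is_approximately_circular(self):
        prof = compute_morphology(_plant(_disk(20)), np.zeros((47, 47), np.uint8))
        assert 0.9 <= prof.circularity <= 1.1
        assert 1.0 <= prof.eccentricity <= 1.05

    def test_ellipse_eccentricity_from_moments(self):
        yy, xx = np.mgrid[-15:16, -45:46]
        mask = xx**2 / 40**2 + yy**2 / 10**2 <= 1.0
        prof = compute_morphology(_plant(mask), np.zeros(mask.shape, np.uint8))
        assert prof.eccentricity == pytest.approx(4.0, abs=0.2)
        assert prof.major_axis == pytest.approx(80.0, rel=0.05)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        blob = rng.random((21, 21)) < 0.5
        blob[10, 10] = True
        base = compute_morphology(_plant(blob), np.zeros((21, 21), np.uint8))
        moved = compute_morphology(
            _plant(blob, offset=(40, 17)), np.zeros((80, 80), np.uint8)
        )
        rot = compute_morphology(
            _plant(np.rot90(blob).copy()), np.zeros((21, 21), np.uint8)
        )
        for other in (moved, rot):
            assert other.area == base.area
            assert other.perimeter == pytest.approx(base.perimeter)
            assert other.circularity == pytest.approx(base.circularity)
            assert other.eccentricity == pytest.approx(base.eccentricity)

    def test_eccentricity_at_least_one(self, rng):
        for _ in range(20):
            m = rng.random((15, 15)) < 0.4
            if not m.any():
                continue
            prof = compute_morphology(_plant(m), np.zeros((15, 15), np.uint8))
            assert prof.eccentricity >= 1.0

    def test_tiny_plants_flagged_degenerate_not_raised(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        prof = compute_morphology(_plant(m), np.full((3, 3), 7, np.uint8))
        assert prof.degenerate and prof.area == 1
        assert math.isnan(prof.circularity)

    def test_hisgreypeak_tie_breaks_low(self):
        m = np.ones((1, 4), bool)
        gray = np.array([[9, 9, 3, 3]], dtype=np.uint8)
        prof = compute_morphology(_plant(m), gray)
        assert prof.hisgreypeak == 3


class TestContourTracing:
    def test_single_pixel_and_domino(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert contour_perimeter(trace_outer_contour(m)) == 0.0
        m[1, 2] = True
        assert contour_perimeter(trace_outer_contour(m)) == pytest.approx(2.0)

    def test_diagonal_pair_uses_sqrt2_steps(self):
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[1, 1] = True
        assert contour_perimeter(trace_outer_contour(m)) == pytest.approx(
            2 * math.sqrt(2)
        )

    def test_holes_are_ignored(self):
        m = np.ones((10, 10), bool)
        m[4:6, 4:6] = False
        assert contour_perimeter(trace_outer_contour(m)) == pytest.approx(36.0)


class TestHueProfiles:
    def test_uniform_hue_concentrates_in_one_class(self):
        mask = np.ones((4, 4), bool)
        frac = hue_class_histogram(_plant(mask), _hsb_raster((4, 4), 0), 16)
        assert frac[0] == 1.0 and frac.sum() == pytest.approx(1.0)

    def test_uniform_coverage_gives_equal_classes(self):
        mask = np.ones((16, 16), bool)
        hsb = _hsb_raster((16, 16), 0)
        hsb[..., 0] = np.arange(256).reshape(16, 16)
        frac = hue_class_histogram(_plant(mask), hsb, 16)
        assert np.allclose(frac, 1 / 16)

    def test_class_index_is_floor_of_scaled_hue(self):
        mask = np.ones((1, 2), bool)
        hsb = _hsb_raster((1, 2), 0)
        hsb[0, 0, 0] = 85  # floor(85*16/256) = 5
        hsb[0, 1, 0] = 20  # floor(20*16/256) = 1
        frac = hue_class_histogram(_plant(mask), hsb, 16)
        assert frac[5] == 0.5 and frac[1] == 0.5

    def test_yellow_damage_fraction_and_flag(self):
        mask = np.ones((4, 4), bool)
        f, damaged = yellow_damage_fraction(_plant(mask), _hsb_raster((4, 4), 20))
        assert f == 1.0 and damaged
        f, damaged = yellow_damage_fraction(_plant(mask), _hsb_raster((4, 4), 85))
        assert f == 0.0 and not damaged
        hsb = _hsb_raster((4, 4), 85)
        hsb[:2, :, 0] = 20  # half yellow -> exactly 0.5, strictly-greater rule
        f, damaged = yellow_damage_fraction(_plant(mask), hsb)
        assert f == 0.5 and not damaged


def _layout_1cell(center=(50.0, 50.0)):
    return PlateLayout(
        "square_grid", 1, 1, np.array([center]), {0: "L"}, (100, 100)
    )


class TestObjectFiltering:
    def test_area_bound_is_strict(self):
        mask39 = np.zeros((10, 10), bool)
        mask39.flat[:39] = True
        comps = label_components(mask39)
        spec = ObjectFilterSpec(min_area=40)
        kept = filter_objects(label_components(np.ones((7, 6), bool)), spec)
        assert len(kept) == 1  # 42 px > 40
        assert filter_objects(comps, spec) == [] or all(
            c.area > 40 for c in filter_objects(comps, spec)
        )

    def test_distance_bound_uses_nearest_cell_center(self):
        m = np.zeros((100, 100), bool)
        m[5:10, 5:10] = True  # centroid (7,7), far from center (50,50)
        comps = label_components(m)
        spec = ObjectFilterSpec(min_area=1, max_dist_to_center=30)
        assert filter_objects(comps, spec, _layout_1cell()) == []
        near = ObjectFilterSpec(min_area=1, max_dist_to_center=90)
        kept = filter_objects(comps, near, _layout_1cell())
        assert len(kept) == 1 and kept[0].cell == 0

    def test_distance_spec_without_layout_raises(self):
        spec = ObjectFilterSpec(max_dist_to_center=10)
        with pytest.raises(ValueError):
            filter_objects([], spec, None)

    def test_elongated_polyline_passes_root_circularity(self):
        m = np.zeros((100, 100), bool)
        m[10:90, 48:51] = True  # 3-px-wide vertical stroke
        comps = label_components(m)
        spec = ObjectFilterSpec(min_area=1, circ_max=0.70)
        assert len(filter_objects(comps, spec)) == 1
        compact = ObjectFilterSpec(min_area=1, circ_min=0.70)
        assert filter_objects(comps, compact) == []

    def test_filtering_is_idempotent_subset(self, rng):
        m = rng.random((60, 60)) < 0.3
        comps = label_components(m)
        spec = ObjectFilterSpec(min_area=3)
        once = filter_objects(comps, spec)
        twice = filter_objects(once, spec)
        assert twice == once
        assert set(c.label for c in once) <= set(c.label for c in comps)


class TestPerCellSelection:
    def test_largest_wins_and_ties_take_lowest_label(self):
        big = _component(np.ones((10, 10), bool), label=1)
        small = _component(np.ones((5, 5), bool), label=2, offset=(20, 20))
        tie = _component(np.ones((10, 10), bool), label=3, offset=(40, 40))
        for c in (big, small, tie):
            c.cell = 0
        layout = _layout_1cell()
        best = select_largest_per_cell([small, tie, big], layout)
        assert best[0].label == 1

    def test_empty_cells_absent(self):
        layout = _layout_1cell()
        assert select_largest_per_cell([], layout) == {}


def _phosphate_layout():
    centers = np.array([[20.0, 40.0], [60.0, 40.0]])
    return PlateLayout("square_grid", 1, 2, centers, {0: "A", 1: "B"}, (200, 100))


class TestShootRootMerge:
    def _shoot(self, x, label=1):
        m = np.ones((6, 6), bool)
        return _component(m, label=label, offset=(20, x - 3))

    def _root(self, x, top, length, label=10):
        m = np.ones((length, 3), bool)
        return _component(m, label=label, offset=(top, x - 1))

    def test_merge_conserves_disjoint_pixels(self):
        shoot = self._shoot(20)
        root = self._root(20, top=40, length=50)
        merged = merge_shoot_root([shoot], [root], _phosphate_layout())
        assert len(merged) == 1
        assert merged[0].area == shoot.area + root.area
        assert set(merged[0].parts) == {"shoot", "root"}

    def test_unpaired_shoot_becomes_shoot_only_plant(self):
        shoot = self._shoot(20)
        merged = merge_shoot_root([shoot], [], _phosphate_layout())
        assert len(merged) == 1 and set(merged[0].parts) == {"shoot"}

    def test_nearest_root_below_centroid_wins(self):
        shoot = self._shoot(20)
        near = self._root(20, top=40, length=30, label=10)
        far = self._root(20, top=90, length=30, label=11)
        merged = merge_shoot_root([shoot], [far, near], _phosphate_layout())
        assert merged[0].parts["root"] is near

    def test_roots_in_other_columns_ignored(self):
        shoot = self._shoot(20)
        other_col = self._root(60, top=40, length=30)
        merged = merge_shoot_root([shoot], [other_col], _phosphate_layout())
        assert set(merged[0].parts) == {"shoot"}

    def test_random_merges_conserve_pixel_counts(self, rng):
        layout = _phosphate_layout()
        for _ in range(50):
            x = int(rng.choice([20, 60]))
            length = int(rng.integers(20, 60))
            shoot = self._shoot(x)
            root = self._root(x, top=int(rng.integers(35, 60)), length=length)
            merged = merge_shoot_root([shoot], [root], layout)
            assert merged[0].area == shoot.area + root.area
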