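"""Grid geometry and occlusion-crop synthesis."""

import numpy as np
import pytest

from occubalance.component_pool import ElementKind
from occubalance.dataset_io import (
    IlluminationLabel,
    OcclusionClass,
    SubDatasetKey,
)
from occubalance.errors import SynthesisError
from occubalance.synthesis import (
    GridSpec,
    LatticePoint,
    edge_entry_points,
    extract_n_crops,
    fruit_overlap_fraction,
    sample_edge_placement,
    sample_fruit_placement,
    synthesize_fruit_occlusion,
    synthesize_fused,
    synthesize_single_occluder,
    valid_endpoints,
    _fruit_canvas_layout,
)

GRID6 = GridSpec.for_crop(120, 120)


def _element(pool, kind, ill=IlluminationLabel.HIGH):
    return pool.element_list(kind, ill)[0]


class TestEdgeEntryPoints:
    def test_six_cell_grid_has_24(self):
        assert len(edge_entry_points(GRID6)) == 24

    @pytest.mark.parametrize("n", range(2, 11))
    def test_matches_brute_force_boundary_enumeration(self, n):
        grid = GridSpec(n, 10.0, 10.0)
        brute = {
            LatticePoint(r, c)
            for r in range(n + 1)
            for c in range(n + 1)
            if r in (0, n) or c in (0, n)
        }
        points = edge_entry_points(grid)
        assert set(points) == brute
        assert len(points) == 4 * n


class TestValidEndpoints:
    @staticmethod
    def _oracle(start, n, min_sep=3):
        return {
            LatticePoint(r, c)
            for r in range(n + 1)
            for c in range(n + 1)
            if r != start.row
            and c != start.col
            and max(abs(r - start.row), abs(c - start.col)) > min_sep
        }

    def test_corner_start_constraints(self):
        ends = valid_endpoints(LatticePoint(0, 0), GRID6)
        assert ends
        for p in ends:
            assert p.row >= 1 and p.col >= 1
            assert max(p.row, p.col) >= 4

    def test_matches_oracle_for_all_boundary_starts(self):
        for start in edge_entry_points(GRID6):
            assert valid_endpoints(start, GRID6) == self._oracle(start, 6)

    def test_mid_edge_exclusions(self):
        ends = valid_endpoints(LatticePoint(0, 3), GRID6)
        assert LatticePoint(4, 3) not in ends  # same column as the start
        assert LatticePoint(3, 6) not in ends  # Chebyshev distance exactly 3
        assert LatticePoint(4, 0) in ends  # distance 4, distinct row and column
        assert LatticePoint(6, 6) in ends  # far corner qualifies


class TestEdgePlacement:
    def test_paste_box_spans_start_end(self, rng):
        for _ in range(100):
            p = sample_edge_placement(GRID6, rng)
            sx, sy = GRID6.pixel(p.start)
            ex, ey = GRID6.pixel(p.end)
            assert p.paste_box.x_min == min(sx, ex)
            assert p.paste_box.y_max == max(sy, ey)
            assert 0.5 <= p.scale <= 1.0
            assert p.start in edge_entry_points(GRID6)


class TestSingleOccluder:
    def test_class_follows_element_kind(self, toy_pool, rng):
        crop = np.full((120, 120, 3), 99, dtype=np.uint8)
        b = synthesize_single_occluder(crop, _element(toy_pool, ElementKind.BRANCH), rng)
        l = synthesize_single_occluder(crop, _element(toy_pool, ElementKind.LEAF), rng)
        assert b.cls is OcclusionClass.B
        assert l.cls is OcclusionClass.L
        assert b.raster.shape == crop.shape

    def test_fruit_element_rejected(self, toy_pool, rng):
        crop = np.zeros((60, 60, 3), dtype=np.uint8)
        with pytest.raises(SynthesisError):
            synthesize_single_occluder(crop, _element(toy_pool, ElementKind.FRUIT), rng)

    def test_pixels_outside_paste_box_unchanged(self, toy_pool, rng):
        crop = (np.indices((120, 120)).sum(axis=0) % 256).astype(np.uint8)
        crop = np.dstack([crop] * 3)
        # replicate the placement draw with an identical generator to
        # recover the paste box independently of the synthesis call
        probe = np.random.default_rng(777)
        placement = sample_edge_placement(GRID6, probe)
        out = synthesize_single_occluder(
            crop, _element(toy_pool, ElementKind.LEAF), np.random.default_rng(777)
        )
        box = placement.paste_box
        changed = np.argwhere((out.raster != crop).any(axis=2))
        for y, x in changed:
            assert box.x_min <= x < box.x_max
            assert box.y_min <= y < box.y_max

    def test_bit_for_bit_reproducible(self, toy_pool):
        crop = np.full((120, 120, 3), 50, dtype=np.uint8)
        el = _element(toy_pool, ElementKind.BRANCH)
        a = synthesize_single_occluder(crop, el, np.random.default_rng(5))
        b = synthesize_single_occluder(crop, el, np.random.default_rng(5))
        np.testing.assert_array_equal(a.raster, b.raster)


class TestFruitPlacement:
    def test_ten_thousand_samples_respect_overlap_bound(self, rng):
        for _ in range(10000):
            p = sample_fruit_placement(GRID6, rng)
            assert p.overlap_fraction <= 0.34

    def test_corner_origin_overlap_value(self):
        # fruit at canvas corner overlaps the central crop on a 2x2-cell
        # square out of the 6x6-cell crop: 4/36
        assert fruit_overlap_fraction(GRID6, (0, 0)) == pytest.approx(4 / 36)

    def test_accepted_cell_corners_match_enumeration(self, rng):
        cell = int(GRID6.cell_w)
        n_x0, n_y0, quad_w, quad_h = _fruit_canvas_layout(GRID6)
        origin = (n_x0 + 60, n_y0 + 60)
        accepted_oracle = set()
        for cx in range(quad_w // cell):
            for cy in range(quad_h // cell):
                corner = (cx * cell, cy * cell)
                frac = fruit_overlap_fraction(GRID6, corner)
                centroid = (corner[0] + 60, corner[1] + 60)
                if frac <= 0.34 and centroid != origin:
                    accepted_oracle.add((cx, cy))
        # cell-resolution acceptance decisions agree with the sampler's rule
        for (cx, cy) in [(x, y) for x in range(7) for y in range(7)]:
            corner = (cx * cell, cy * cell)
            frac = fruit_overlap_fraction(GRID6, corner)
            centroid_hit = (corner[0] + 60, corner[1] + 60) == origin
            assert ((cx, cy) in accepted_oracle) == (frac <= 0.34 and not centroid_hit)

    def test_centered_corner_rejected(self):
        # corner 4 cells in centers the fruit exactly on the crop
        assert fruit_overlap_fraction(GRID6, (80, 80)) == pytest.approx(1.0)


class TestFruitSynthesis:
    def test_output_size_equals_input(self, toy_pool, rng):
        crop = np.full((120, 120, 3), 10, dtype=np.uint8)
        out = synthesize_fruit_occlusion(crop, _element(toy_pool, ElementKind.FRUIT), rng)
        assert out.cls is OcclusionClass.F
        assert out.raster.shape == crop.shape

    def test_changed_pixels_bounded_by_34_percent(self, toy_pool, rng):
        crop = np.full((120, 120, 3), 10, dtype=np.uint8)
        for _ in range(20):
            out = synthesize_fruit_occlusion(crop, _element(toy_pool, ElementKind.FRUIT), rng)
            changed = (out.raster != crop).any(axis=2).sum()
            assert changed <= 0.34 * 120 * 120

    def test_opaque_square_mask_changes_exact_intersection(self, toy_pool):
        from occubalance.component_pool import Element

        crop = np.full((120, 120, 3), 10, dtype=np.uint8)
        square = np.zeros((40, 40, 4), dtype=np.uint8)
        square[:, :, :3] = 200
        square[:, :, 3] = 255
        fruit = Element(ElementKind.FRUIT, IlluminationLabel.HIGH, square, "sq")
        probe = np.random.default_rng(42)
        placement = sample_fruit_placement(GRID6, probe)
        out = synthesize_fruit_occlusion(crop, fruit, np.random.default_rng(42))
        changed = int((out.raster != crop).any(axis=2).sum())
        expected = int(round(placement.overlap_fraction * 120 * 120))
        assert changed == expected


class TestFused:
    @pytest.mark.parametrize(
        "cls,kinds",
        [
            (OcclusionClass.BL, ["branch", "leaf"]),
            (OcclusionClass.BF, ["fruit", "branch"]),
            (OcclusionClass.LF, ["fruit", "leaf"]),
            (OcclusionClass.BLF, ["fruit", "branch", "leaf"]),
        ],
    )
    def test_sequential_provenance_lists_step_elements(self, toy_pool, rng, cls, kinds):
        crop = np.full((120, 120, 3), 77, dtype=np.uint8)
        out = synthesize_fused(crop, cls, toy_pool, IlluminationLabel.HIGH, rng)
        assert out.cls is cls
        assert out.provenance.element_kinds == kinds
        assert len(out.provenance.element_source_ids) == len(kinds)

    def test_composite_route_uses_one_composite(self, toy_pool, rng):
        crop = np.full((120, 120, 3), 77, dtype=np.uint8)
        out = synthesize_fused(
            crop, OcclusionClass.BLF, toy_pool, IlluminationLabel.HIGH, rng,
            route="composite_element",
        )
        assert out.provenance.element_kinds == ["composite"]
        assert out.cls is OcclusionClass.BLF

    def test_sequential_bf_composes_single_steps(self, toy_pool):
        from occubalance.component_pool import sample_element

        crop = np.full((120, 120, 3), 77, dtype=np.uint8)
        fused = synthesize_fused(
            crop, OcclusionClass.BF, toy_pool, IlluminationLabel.HIGH,
            np.random.default_rng(31),
        )
        # replay the identical draw sequence through the two single-step ops
        replay = np.random.default_rng(31)
        fruit = sample_element(toy_pool, ElementKind.FRUIT, IlluminationLabel.HIGH, replay)
        step1 = synthesize_fruit_occlusion(crop, fruit, replay)
        branch = sample_element(toy_pool, ElementKind.BRANCH, IlluminationLabel.HIGH, replay)
        step2 = synthesize_single_occluder(step1.raster, branch, replay)
        np.testing.assert_array_equal(fused.raster, step2.raster)

    def test_non_fused_class_rejected(self, toy_pool, rng):
        crop = np.zeros((60, 60, 3), dtype=np.uint8)
        with pytest.raises(SynthesisError):
            synthesize_fused(crop, OcclusionClass.B, toy_pool, IlluminationLabel.HIGH, rng)


class TestExtractNCrops:
    @staticmethod
    def _three_n_dataset():
        from occubalance.dataset_io import Annotation, BBox, Dataset, ImageRecord

        raster = np.arange(40 * 40 * 3, dtype=np.uint8).reshape(40, 40, 3) % 251
        boxes = [BBox(0, 0, 10, 10), BBox(10, 0, 22, 14), BBox(0, 20, 16, 36)]
        record = ImageRecord(
            image_id="src", path=None, width=40, height=40, region="AA",
            annotations=[Annotation(b, OcclusionClass.N) for b in boxes],
            illumination=IlluminationLabel.HIGH, raster=raster,
        )
        return Dataset([record]), boxes

    def test_round_robin_multiplicities(self, rng):
        # 3 available substrates, 7 requested -> reuse counts {3, 2, 2}
        ds, boxes = self._three_n_dataset()
        key = SubDatasetKey("AA", IlluminationLabel.HIGH)
        crops = extract_n_crops(ds, key, 7, rng)
        by_size = {}
        for crop in crops:
            by_size[crop.shape[:2]] = by_size.get(crop.shape[:2], 0) + 1
        assert sorted(by_size.values(), reverse=True) == [3, 2, 2]
        assert set(by_size) == {(b.height, b.width) for b in boxes}

    def test_count_zero(self, toy_dataset, rng):
        key = SubDatasetKey("AA", IlluminationLabel.HIGH)
        assert extract_n_crops(toy_dataset, key, 0, rng) == []

    def test_crop_sizes_match_boxes(self, toy_dataset, rng):
        key = SubDatasetKey("AA", IlluminationLabel.LOW)
        crops = extract_n_crops(toy_dataset, key, 5, rng)
        n_boxes = [
            a.box
            for r in toy_dataset
            if r.region == "AA" and r.illumination is IlluminationLabel.LOW
            for a in r.annotations
            if a.cls is OcclusionClass.N
        ]
        sizes = {(b.height, b.width) for b in n_boxes}
        for crop in crops:
            assert crop.shape[:2] in sizes

    def test_no_n_boxes_errors(self, rng):
        from occubalance.dataset_io import Dataset

        key = SubDatasetKey("ZZ", IlluminationLabel.HIGH)
        with pytest.raises(SynthesisError):
            extract_n_crops(Dataset([]), key, 1, rng)
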