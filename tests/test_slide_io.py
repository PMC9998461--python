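"""Slide abstraction, Otsu tissue detection, cropping and annotation I/O."""

import json

import numpy as np
import pytest

from cervicad.slide_io import (Box, Region, SlideImage, crop_and_resize, detect_fragments,
                               otsu_tissue_mask, points_in_polygon, rasterize_polygons,
                               read_annotations, read_mask, unwarp_mask_to_level0,
                               warp_mask_to_crop, write_annotations, write_mask)


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance maximisation over all 256 levels."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t) * hist[:t]).sum() / w0
        mu1 = (np.arange(t, 256) * hist[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_pure_white_image_is_all_background(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        assert otsu_tissue_mask(img).sum() == 0

    def test_dark_square_recovered(self):
        img = np.full((300, 300, 3), 250, dtype=np.uint8)
        img[100:200, 50:150] = 40
        mask = otsu_tissue_mask(img)
        truth = np.zeros((300, 300), bool)
        truth[100:200, 50:150] = True
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_threshold_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        gray = np.concatenate([
            np.clip(rng.normal(70, 12, 4000), 0, 255),
            np.clip(rng.normal(190, 15, 6000), 0, 255),
        ]).astype(np.uint8).reshape(100, 100)
        mask = otsu_tissue_mask(gray)
        t_star = brute_force_otsu(gray)
        # the mask must equal "below threshold" for some t within 1 level
        candidates = [gray < (t_star + d) for d in (-1, 0, 1)]
        assert any(np.array_equal(mask, c) for c in candidates)


class TestFragments:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((100, 200), bool)
        mask[10:40, 10:60] = True
        mask[60:90, 120:180] = True
        assert len(detect_fragments(mask)) == 2

    def test_min_area_excludes_small_blob(self):
        mask = np.zeros((100, 100), bool)
        mask[10:40, 10:40] = True
        mask[80:83, 80:83] = True
        boxes = detect_fragments(mask, min_area=200)
        assert len(boxes) == 1
        assert boxes[0] == Box(10, 10, 40, 40)

    def test_phantom_fragments_recovered(self, small_cfg):
        """Three generated fragments yield three boxes covering the truth."""
        import dataclasses

        from cervicad.labels import OrdinalLabel
        from cervicad.phantom import generate_phantom_slide

        cfg = dataclasses.replace(small_cfg, image_size=(900, 700),
                                  fragments_per_slide=(3, 3))
        ph = generate_phantom_slide(cfg, OrdinalLabel.LSIL, seed=21)
        mask = otsu_tissue_mask(ph.image)
        boxes = detect_fragments(mask, min_area=0.0005 * mask.size)
        assert len(boxes) == len(ph.fragment_boxes) == 3
        for found, truth in zip(boxes, sorted(ph.fragment_boxes, key=lambda b: (b.y0, b.x0))):
            ix = max(0, min(found.x1, truth.x1) - max(found.x0, truth.x0))
            iy = max(0, min(found.y1, truth.y1) - max(found.y0, truth.y0))
            assert ix * iy >= 0.9 * truth.area


class TestCropAndResize:
    def _slide(self, w=2200, h=2200):
        rng = np.random.default_rng(0)
        return SlideImage(rng.integers(0, 255, size=(h, w, 3), dtype=np.uint8))

    def test_square_box_scale(self):
        crop = crop_and_resize(self._slide(), Box(100, 100, 612, 612), size=1024)
        assert crop.scale_x == crop.scale_y == 0.5
        assert crop.image.shape == (1024, 1024, 3)

    def test_wide_box_padded_to_square(self):
        crop = crop_and_resize(self._slide(2200, 1100), Box(0, 0, 2048, 1024), size=1024)
        assert crop.scale_x == crop.scale_y == 2.0  # 2048-px padded side over 1024
        assert crop.pad_top == (2048 - 1024) // 2

    def test_round_trip_maps_center_to_center(self):
        box = Box(40, 60, 552, 360)
        crop = crop_and_resize(self._slide(800, 600), box, size=256)
        cx, cy = crop.to_level0(128, 128)
        assert abs(cx - (box.x0 + box.x1) / 2) <= 1
        assert abs(cy - (box.y0 + box.y1) / 2) <= 1
        px, py = crop.from_level0(cx, cy)
        assert abs(px - 128) <= 1e-6 and abs(py - 128) <= 1e-6

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            crop_and_resize(self._slide(100, 100), Box(5, 5, 5, 50))

    def test_mask_warp_unwarp_round_trip(self):
        slide = self._slide(400, 300)
        mask = np.zeros((300, 400), bool)
        mask[100:180, 50:250] = True
        box = Box(30, 80, 280, 220)
        crop = crop_and_resize(slide, box, size=128)
        warped = warp_mask_to_crop(crop, mask)
        back = unwarp_mask_to_level0(crop, warped, (300, 400))
        inside = mask[box.y0:box.y1, box.x0:box.x1]
        recovered = back[box.y0:box.y1, box.x0:box.x1]
        dice = 2 * (inside & recovered).sum() / (inside.sum() + recovered.sum())
        assert dice > 0.95


class TestPyramid:
    def test_downsamples_increase_from_one(self):
        slide = SlideImage(np.zeros((1024, 2048, 3), np.uint8))
        assert slide.level_downsamples[0] == 1.0
        assert all(a < b for a, b in zip(slide.level_downsamples, slide.level_downsamples[1:]))

    def test_level_for_20x_is_downsample_two(self):
        slide = SlideImage(np.zeros((1024, 1024, 3), np.uint8), base_magnification=40)
        level = slide.level_for_magnification(20)
        assert slide.level_downsamples[level] == 2.0

    def test_read_region_pads_with_white_and_flags(self):
        slide = SlideImage(np.zeros((64, 64, 3), np.uint8))
        region, padded = slide.read_region(0, -16, -16, 32, 32)
        assert padded
        assert (region[:16, :16] == 255).all()
        assert (region[16:, 16:] == 0).all()


class TestMaskAndAnnotations:
    def test_mask_png_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        mask = rng.random((64, 80)) > 0.5
        write_mask(tmp_path / "m.png", mask)
        np.testing.assert_array_equal(read_mask(tmp_path / "m.png"), mask)

    def test_unit_square_rasterises_100_pixels(self):
        poly = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        mask = rasterize_polygons([poly], (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_empty_feature_collection_gives_zero_mask(self, tmp_path):
        (tmp_path / "a.geojson").write_text(json.dumps(
            {"type": "FeatureCollection", "features": []}))
        regions = read_annotations(tmp_path / "a.geojson")
        assert regions == []
        assert rasterize_polygons([r.polygon for r in regions], (8, 8)).sum() == 0

    def test_annotations_round_trip(self, tmp_path):
        regions = [Region(np.array([[1.0, 2.0], [30.0, 2.0], [30.0, 25.0]]), "HSIL")]
        write_annotations(tmp_path / "r.geojson", regions)
        loaded = read_annotations(tmp_path / "r.geojson")
        assert loaded[0].label == "HSIL"
        np.testing.assert_allclose(loaded[0].polygon, regions[0].polygon)

    def test_malformed_geojson_is_descriptive(self, tmp_path):
        (tmp_path / "bad.geojson").write_text("{not json")
        with pytest.raises(ValueError, match="malformed GeoJSON"):
            read_annotations(tmp_path / "bad.geojson")

    def test_point_in_polygon_even_odd(self):
        ring = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        pts = np.array([[5, 5], [15, 5], [0.5, 0.5]])
        np.testing.assert_array_equal(points_in_polygon(pts, ring), [True, False, True])
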