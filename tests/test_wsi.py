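"""Stage-2 pipeline: thresholded tissue masks, tile enumeration against a
brute-force oracle, probability stitching, and overlay rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tissuegrid as tg
from tissuegrid.wsi import TileGrid


def _full_mask(h, w, ds=1):
    return tg.TissueMask(np.ones((int(np.ceil(h / ds)), int(np.ceil(w / ds))),
                                 dtype=np.uint8), ds, "fixed_threshold")


class TestTissueMask:
    def test_all_white_slide_gives_empty_mask_with_warning(self):
        slide = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning, match="blank"):
            mask = tg.compute_tissue_mask(slide, downsample=8)
        assert mask.mask.sum() == 0

    def test_mosaic_mask_recovers_tissue_region(self):
        layout = tg.quadrant_mosaic_layout(256, margin=32)
        slide, truth = tg.generate_mosaic_slide(layout, tg.easy_preset()[:4], 2)
        mask = tg.compute_tissue_mask(slide, downsample=16)
        pred = mask.at_full_resolution(truth.shape).astype(bool)
        true = truth != tg.BACKGROUND_LABEL
        iou = (pred & true).sum() / (pred | true).sum()
        assert iou >= 0.95

    def test_fixed_threshold_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        # values away from the threshold so the complement is exact
        gray = np.where(rng.random((32, 32)) < 0.5, 0.2, 0.9)
        slide = (np.stack([gray] * 3, axis=-1) * 255).astype(np.uint8)
        m = tg.compute_tissue_mask(slide, 1, "fixed_threshold", 0.5)
        inv = tg.compute_tissue_mask(255 - slide, 1, "fixed_threshold", 0.5)
        np.testing.assert_array_equal(m.mask, 1 - inv.mask)

    def test_downsampled_dims_use_ceiling(self):
        slide = np.zeros((70, 50, 3), dtype=np.uint8)
        m = tg.compute_tissue_mask(slide, 32, "fixed_threshold", 0.5)
        assert m.mask.shape == (3, 2)

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            tg.compute_tissue_mask(np.zeros((8, 8, 3), dtype=np.uint8),
                                   1, "watershed")


def _brute_force_tiles(mask_full, tile, stride, frac):
    H, W = mask_full.shape
    out = []
    for r in range(0, H - tile + 1, stride):
        for c in range(0, W - tile + 1, stride):
            if mask_full[r:r + tile, c:c + tile].mean() >= frac:
                out.append((r, c))
    return out


class TestEnumerateTiles:
    def test_single_exact_tile(self):
        grid = tg.enumerate_tiles(_full_mask(224, 224), (224, 224), 224, 128)
        assert grid.coords == [(0, 0)]

    def test_480_slide_gives_nine_tiles(self):
        grid = tg.enumerate_tiles(_full_mask(480, 480), (480, 480), 224, 128)
        assert len(grid.coords) == 9
        assert grid.coords == [(r, c) for r in (0, 128, 256)
                               for c in (0, 128, 256)]

    def test_empty_mask_gives_no_tiles(self):
        mask = tg.TissueMask(np.zeros((10, 10), dtype=np.uint8), 1, "otsu_gray")
        assert tg.enumerate_tiles(mask, (10, 10), 4, 2).coords == []

    def test_tile_larger_than_slide_rejected(self):
        with pytest.raises(ValueError):
            tg.enumerate_tiles(_full_mask(10, 10), (10, 10), 16, 4)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(8, 40), st.integers(8, 40), st.integers(2, 10),
           st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration(self, H, W, tile, stride, seed):
        tile = min(tile, H, W)
        mask_full = (np.random.default_rng(seed).random((H, W)) < 0.7) \
            .astype(np.uint8)
        mask = tg.TissueMask(mask_full, 1, "fixed_threshold")
        grid = tg.enumerate_tiles(mask, (H, W), tile, stride, 0.5)
        assert grid.coords == _brute_force_tiles(mask_full, tile, stride, 0.5)

    def test_count_formula_under_full_mask(self):
        H, W, tile, stride = 70, 55, 16, 9
        grid = tg.enumerate_tiles(_full_mask(H, W), (H, W), tile, stride, 0.5)
        expected = ((H - tile) // stride + 1) * ((W - tile) // stride + 1)
        assert len(grid.coords) == expected


class TestClassifyTiles:
    def test_rows_sum_to_one_and_batching_invariant(self, tiny_model, rng):
        slide = rng.integers(0, 255, size=(48, 48, 3), dtype=np.uint8)
        grid = tg.enumerate_tiles(_full_mask(48, 48), (48, 48), 16, 16)
        p1 = tg.classify_tiles(tiny_model, slide, grid, batch_size=1)
        p32 = tg.classify_tiles(tiny_model, slide, grid, batch_size=32)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(p1, p32, atol=1e-5)

    def test_oracle_rows_one_hot_at_true_labels(self):
        truth = np.zeros((32, 32), dtype=np.int64)
        truth[:, 16:] = 1
        oracle = tg.OracleTileClassifier(truth, 2)
        grid = TileGrid(16, 16, [(0, 0), (0, 16), (16, 0), (16, 16)], 0.5)
        probs = tg.classify_tiles(oracle, np.zeros((32, 32, 3), np.uint8), grid)
        np.testing.assert_allclose(probs, [[1, 0], [0, 1], [1, 0], [0, 1]])

    def test_tile_size_model_mismatch_rejected(self, tiny_model):
        grid = TileGrid(32, 32, [(0, 0)], 0.5)
        with pytest.raises(ValueError, match="tile size"):
            tg.classify_tiles(tiny_model, np.zeros((32, 32, 3), np.uint8), grid)


class TestStitch:
    def test_single_covering_tile_constant_map(self):
        grid = TileGrid(8, 8, [(0, 0)], 0.5)
        seg = tg.stitch_segmentation(grid, np.array([[0.0, 1.0, 0.0]]), (8, 8))
        assert np.all(seg.label_map == 1)

    def test_overlap_averages_probabilities(self):
        """Two tiles with probs [0.6, 0.4] and [0.2, 0.8]: the overlap
        averages to [0.4, 0.6] and labels as class 1."""
        grid = TileGrid(4, 2, [(0, 0), (0, 2)], 0.5)
        probs = np.array([[0.6, 0.4], [0.2, 0.8]])
        seg = tg.stitch_segmentation(grid, probs, (4, 6))
        assert np.all(seg.label_map[:, 0:2] == 0)     # first tile only
        assert np.all(seg.label_map[:, 2:4] == 1)     # averaged overlap
        assert np.all(seg.label_map[:, 4:6] == 1)     # second tile only
        norm = seg.prob_field[:, 0, 2] / seg.coverage[0, 2]
        np.testing.assert_allclose(norm, [0.4, 0.6])

    def test_overlap_matches_per_pixel_brute_force(self, rng):
        tile, H, W = 6, 12, 12
        coords = [(r, c) for r in (0, 3, 6) for c in (0, 3, 6)]
        probs = rng.random((len(coords), 3))
        probs /= probs.sum(axis=1, keepdims=True)
        seg = tg.stitch_segmentation(TileGrid(tile, 3, coords, 0.5), probs,
                                     (H, W))
        acc = np.zeros((3, H, W))
        cov = np.zeros((H, W))
        for (r, c), p in zip(coords, probs):
            acc[:, r:r + tile, c:c + tile] += p[:, None, None]
            cov[r:r + tile, c:c + tile] += 1
        for y in range(H):
            for x in range(W):
                if cov[y, x]:
                    assert seg.label_map[y, x] == np.argmax(acc[:, y, x] / cov[y, x])
                else:
                    assert seg.label_map[y, x] == tg.BACKGROUND_LABEL

    def test_normalized_probabilities_sum_to_one_at_covered_pixels(self, rng):
        coords = [(0, 0), (0, 4), (4, 0)]
        probs = rng.random((3, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        seg = tg.stitch_segmentation(TileGrid(8, 4, coords, 0.5), probs, (12, 12))
        covered = seg.coverage > 0
        norm = seg.prob_field[:, covered] / seg.coverage[covered]
        np.testing.assert_allclose(norm.sum(axis=0), 1.0, atol=1e-6)

    def test_ties_break_to_lowest_class(self):
        seg = tg.stitch_segmentation(TileGrid(4, 4, [(0, 0)], 0.5),
                                     np.array([[0.5, 0.5]]), (4, 4))
        assert np.all(seg.label_map == 0)

    def test_non_overlapping_stitch_equals_per_tile_argmax(self, tiny_model,
                                                           rng):
        """With stride = tile size the averaging scheme reduces exactly to
        each tile's own argmax."""
        slide = rng.integers(0, 255, size=(48, 48, 3), dtype=np.uint8)
        grid = tg.enumerate_tiles(_full_mask(48, 48), (48, 48), 16, 16)
        probs = tg.classify_tiles(tiny_model, slide, grid)
        seg = tg.stitch_segmentation(grid, probs, (48, 48))
        for (r, c), p in zip(grid.coords, probs):
            assert np.all(seg.label_map[r:r + 16, c:c + 16] == p.argmax())

    def test_misaligned_probs_rejected(self):
        with pytest.raises(ValueError):
            tg.stitch_segmentation(TileGrid(4, 4, [(0, 0)], 0.5),
                                   np.ones((2, 3)) / 3, (4, 4))


class TestOverlay:
    def _seg(self):
        grid = TileGrid(4, 4, [(0, 0)], 0.5)
        return tg.stitch_segmentation(grid, np.array([[0.0, 1.0]]), (4, 8))

    def test_alpha_zero_is_identity(self, rng):
        slide = rng.integers(0, 255, size=(4, 8, 3), dtype=np.uint8)
        out = tg.render_overlay(self._seg(), slide, {1: (255, 0, 0)}, alpha=0.0)
        np.testing.assert_array_equal(out, slide)

    def test_alpha_one_paints_constant_color(self, rng):
        slide = rng.integers(0, 255, size=(4, 8, 3), dtype=np.uint8)
        out = tg.render_overlay(self._seg(), slide, {1: (10, 20, 30)}, alpha=1.0)
        assert np.all(out[:, :4] == (10, 20, 30))
        np.testing.assert_array_equal(out[:, 4:], slide[:, 4:])  # background

    def test_blend_formula_per_pixel(self, rng):
        slide = rng.integers(0, 255, size=(4, 8, 3), dtype=np.uint8)
        alpha, color = 0.3, (100, 150, 200)
        out = tg.render_overlay(self._seg(), slide, {1: color}, alpha=alpha)
        expected = np.clip(
            ((1 - alpha) * slide[:, :4] + alpha * np.array(color)).round(),
            0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out[:, :4], expected)

    def test_missing_palette_entry_rejected(self, rng):
        slide = rng.integers(0, 255, size=(4, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="palette"):
            tg.render_overlay(self._seg(), slide, {0: (1, 2, 3)}, alpha=0.5)
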