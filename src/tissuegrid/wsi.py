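"""Two-stage whole-slide segmentation: threshold tissue masking on a
downsampled slide, overlapping tile enumeration (default 224 px tiles at
stride 128), per-tile classification, and probability stitching into a
patch-level label map.

Overlapping tile predictions are combined by *averaging* the accumulated
class probabilities at each pixel before taking the argmax; with
non-overlapping tiles this reduces exactly to per-tile argmax.  Pixels not
covered by any kept tile carry the reserved background label.

The pipeline consumes plain 2-D RGB arrays; pyramidal WSI containers can be
adapted by reading a level into an array first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu

from .common import BACKGROUND_LABEL, check_rgb_image

__all__ = [
    "TissueMask",
    "TileGrid",
    "SegmentationMap",
    "compute_tissue_mask",
    "enumerate_tiles",
    "classify_tiles",
    "stitch_segmentation",
    "render_overlay",
    "segment_slide",
]


@dataclass
class TissueMask:
    """Binary tissue/background map at an integer downsample factor."""

    mask: np.ndarray  # 2-D uint8/bool, 1 = tissue
    downsample: int
    method: str

    def at_full_resolution(self, dims: tuple[int, int]) -> np.ndarray:
        """Nearest-neighbour upsample cropped to the slide dimensions."""
        up = np.kron(self.mask.astype(np.uint8),
                     np.ones((self.downsample, self.downsample), dtype=np.uint8))
        return up[: dims[0], : dims[1]]


@dataclass
class TileGrid:
    """Row-major (row, col) top-left tile corners at full resolution,
    half-open footprints [r, r+tile) x [c, c+tile)."""

    tile_size: int
    stride: int
    coords: list[tuple[int, int]]
    tissue_frac_min: float


@dataclass
class SegmentationMap:
    """Per-pixel class labels plus the accumulated probability field.

    ``label_map`` holds class ids with BACKGROUND_LABEL at uncovered
    pixels; ``prob_field`` is (n_classes, H, W) of *summed* tile
    probabilities and ``coverage`` counts covering tiles per pixel, so the
    normalized field is prob_field / coverage where coverage > 0.
    """

    label_map: np.ndarray
    prob_field: np.ndarray
    coverage: np.ndarray
    background_label: int = BACKGROUND_LABEL


def _block_reduce_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor x factor blocks, edge-padded to a full block."""
    H, W = img.shape[:2]
    ph = (-H) % factor
    pw = (-W) % factor
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="edge")
    h, w = img.shape[0] // factor, img.shape[1] // factor
    return img.reshape(h, factor, w, factor, *img.shape[2:]).mean(axis=(1, 3))


def compute_tissue_mask(slide: np.ndarray, downsample: int = 32,
                        method: str = "otsu_saturation",
                        fixed_threshold: float = 0.8) -> TissueMask:
    """Threshold-based tissue/background separation on a downsampled slide.

    ``otsu_saturation`` (default) thresholds the HSV saturation channel
    (tissue is more saturated than the near-white background);
    ``otsu_gray`` thresholds grayscale brightness (tissue darker);
    ``fixed_threshold`` marks pixels with grayscale < threshold as tissue.
    A blank (constant) slide yields an all-zero mask with a warning.
    """
    slide = check_rgb_image(slide, "slide")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    small = np.asarray(slide, dtype=float)
    if slide.dtype == np.uint8:
        small = small / 255.0
    if downsample > 1:
        small = _block_reduce_mean(small, downsample)

    if method == "otsu_saturation":
        channel = rgb2hsv(small)[..., 1]
        tissue_is_high = True
    elif method == "otsu_gray":
        channel = rgb2gray(small)
        tissue_is_high = False
    elif method == "fixed_threshold":
        channel = rgb2gray(small)
        mask = channel < fixed_threshold
        return TissueMask(mask.astype(np.uint8), downsample, method)
    else:
        raise ValueError(f"unknown masking method {method!r}")

    if np.ptp(channel) < 1e-9:
        warnings.warn("slide appears blank (constant); returning empty tissue mask")
        return TissueMask(np.zeros(channel.shape, dtype=np.uint8), downsample, method)
    t = threshold_otsu(channel)
    mask = channel > t if tissue_is_high else channel < t
    return TissueMask(mask.astype(np.uint8), downsample, method)


def enumerate_tiles(mask: TissueMask, slide_dims: tuple[int, int],
                    tile_size: int = 224, stride: int = 128,
                    tissue_frac_min: float = 0.5) -> TileGrid:
    """All grid-aligned tiles fully inside the slide whose tissue fraction
    (from the upsampled mask) reaches ``tissue_frac_min``; edge windows
    that would overrun the slide are dropped, not padded."""
    H, W = slide_dims
    if tile_size > H or tile_size > W:
        raise ValueError(f"tile_size {tile_size} exceeds slide dims {slide_dims}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    full = mask.at_full_resolution((H, W)).astype(np.int64)
    # summed-area table for O(1) per-tile tissue counts
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    sat[1:, 1:] = full.cumsum(0).cumsum(1)
    area = tile_size * tile_size
    coords = []
    for r in range(0, H - tile_size + 1, stride):
        for c in range(0, W - tile_size + 1, stride):
            r1, c1 = r + tile_size, c + tile_size
            count = sat[r1, c1] - sat[r, c1] - sat[r1, c] + sat[r, c]
            if count / area >= tissue_frac_min:
                coords.append((r, c))
    return TileGrid(tile_size, stride, coords, tissue_frac_min)


def classify_tiles(model, slide: np.ndarray, grid: TileGrid,
                   batch_size: int = 32) -> np.ndarray:
    """Per-tile class probabilities, one row per grid coordinate.

    ``model`` is either a classifier with ``predict_proba(images)`` (its
    input size must equal the grid's tile size) or a coordinate-aware
    callable ``f(tiles, coords) -> probs`` (e.g. a ground-truth oracle).
    """
    slide = check_rgb_image(slide, "slide")
    t = grid.tile_size
    has_predict = hasattr(model, "predict_proba")
    if has_predict and getattr(model, "config", None) is not None:
        if model.config.input_size != t:
            raise ValueError(
                f"model input size {model.config.input_size} != tile size {t}"
            )
    rows = []
    for start in range(0, len(grid.coords), batch_size):
        chunk = grid.coords[start : start + batch_size]
        tiles = np.stack([slide[r : r + t, c : c + t] for r, c in chunk])
        if has_predict:
            rows.append(model.predict_proba(tiles))
        else:
            rows.append(model(tiles, chunk))
    if not rows:
        return np.zeros((0, 0))
    return np.vstack(rows)


def stitch_segmentation(grid: TileGrid, probs: np.ndarray,
                        slide_dims: tuple[int, int]) -> SegmentationMap:
    """Accumulate tile probabilities over their footprints and label each
    covered pixel by the argmax of the coverage-averaged probabilities
    (ties break to the lowest class id); uncovered pixels keep the
    reserved background label."""
    H, W = slide_dims
    probs = np.asarray(probs, dtype=float)
    if len(grid.coords) != len(probs):
        raise ValueError(
            f"{len(probs)} probability rows for {len(grid.coords)} tiles"
        )
    if len(grid.coords) == 0:
        return SegmentationMap(
            np.full((H, W), BACKGROUND_LABEL, dtype=np.int64),
            np.zeros((0, H, W)), np.zeros((H, W), dtype=np.int64))
    n_classes = probs.shape[1]
    t = grid.tile_size
    field = np.zeros((n_classes, H, W))
    coverage = np.zeros((H, W), dtype=np.int64)
    for (r, c), p in zip(grid.coords, probs):
        field[:, r : r + t, c : c + t] += p[:, None, None]
        coverage[r : r + t, c : c + t] += 1
    label_map = np.full((H, W), BACKGROUND_LABEL, dtype=np.int64)
    covered = coverage > 0
    label_map[covered] = field[:, covered].argmax(axis=0)
    return SegmentationMap(label_map, field, coverage)


def render_overlay(seg: SegmentationMap, slide: np.ndarray,
                   palette: dict[int, tuple[int, int, int]],
                   alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend per-class palette colours over the slide; background
    pixels are left untouched (rendered transparent)."""
    slide = check_rgb_image(slide, "slide")
    present = set(np.unique(seg.label_map)) - {seg.background_label}
    missing = present - set(palette)
    if missing:
        raise ValueError(f"palette lacks entries for classes {sorted(missing)}")
    out = np.asarray(slide, dtype=float).copy()
    for class_id in present:
        sel = seg.label_map == class_id
        color = np.asarray(palette[class_id], dtype=float)
        out[sel] = (1 - alpha) * out[sel] + alpha * color
    if slide.dtype == np.uint8:
        return np.clip(out.round(), 0, 255).astype(np.uint8)
    return out


def segment_slide(model, slide: np.ndarray, tile_size: int = 224,
                  stride: int = 128, downsample: int = 32,
                  method: str = "otsu_saturation",
                  tissue_frac_min: float = 0.5, batch_size: int = 32):
    """Full stage-2 pipeline: mask -> tiles -> classify -> stitch.

    Returns (SegmentationMap, TileGrid, per-tile probabilities).
    """
    dims = slide.shape[:2]
    mask = compute_tissue_mask(slide, downsample, method)
    grid = enumerate_tiles(mask, dims, tile_size, stride, tissue_frac_min)
    probs = classify_tiles(model, slide, grid, batch_size)
    seg = stitch_segmentation(grid, probs, dims)
    return seg, grid, probs
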