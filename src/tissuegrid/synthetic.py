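"""Synthetic texture patches and mosaic pseudo-slides.

The generator emulates the statistical structure that makes multitissue
patch classification hard: large *intraclass* variability (every draw from a
class jitters orientation, frequency, tint, and phase) and small
*interclass* variability (the "hard" preset gives neighbouring classes
overlapping parameter ranges, so classes differ mainly in the *joint*
orientation x frequency statistics that second-order feature interactions
can capture, not in mean colour).

Mosaic pseudo-slides place textured rectangular or polygonal regions on a
near-white noisy background — mimicking the bright background of an
H&E-stained slide — with a pixel-exact ground-truth label map, so the whole
mask → tile → classify → stitch pipeline is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .common import BACKGROUND_LABEL

__all__ = [
    "TextureClassSpec",
    "MosaicLayout",
    "generate_patch",
    "generate_patch_dataset",
    "generate_mosaic_slide",
    "easy_preset",
    "hard_preset",
    "blob_task",
    "quadrant_mosaic_layout",
    "OracleTileClassifier",
    "orientation_statistic",
]

_FAMILIES = ("stripes", "blobs", "checker", "smooth_tint", "noise")

# Per-family default parameter ranges.  Scalar params are (lo, hi) intervals;
# "tint" is a triple of per-channel (lo, hi) intervals, values in [0, 1].
_DEFAULTS: dict[str, dict] = {
    "stripes": {
        "orientation": (0.0, 180.0),   # degrees
        "frequency": (0.05, 0.25),     # cycles per pixel
        "contrast": (0.4, 0.8),
        "noise_std": (0.02, 0.05),
        "tint": ((0.7, 0.9), (0.4, 0.6), (0.5, 0.7)),
    },
    "blobs": {
        "radius": (3.0, 6.0),          # pixels
        "density": (0.004, 0.01),      # blobs per pixel^2
        "darkness": (0.4, 0.7),
        "noise_std": (0.02, 0.05),
        "tint": ((0.6, 0.8), (0.4, 0.6), (0.7, 0.9)),
    },
    "checker": {
        "cell": (3.0, 8.0),            # pixels per cell
        "contrast": (0.3, 0.6),
        "noise_std": (0.02, 0.05),
        "tint": ((0.4, 0.6), (0.7, 0.9), (0.4, 0.6)),
    },
    "smooth_tint": {
        "slope": (0.05, 0.25),         # total ramp across the patch
        "noise_std": (0.0, 0.015),
        "tint": ((0.5, 0.7), (0.6, 0.8), (0.8, 1.0)),
    },
    "noise": {
        "noise_std": (0.1, 0.2),
        "tint": ((0.55, 0.75), (0.55, 0.75), (0.55, 0.75)),
    },
}


@dataclass
class TextureClassSpec:
    """One texture class: a family plus per-class parameter intervals.

    ``jitter`` in [0, 1] scales the within-class sampling spread: 1 samples
    uniformly over each interval, 0 pins every parameter to its midpoint
    (two draws then differ only through pixel noise, or not at all when the
    noise interval is also degenerate).
    """

    class_id: int
    family: str
    param_ranges: dict = field(default_factory=dict)
    jitter: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown texture family {self.family!r}; "
                             f"choose from {_FAMILIES}")
        merged = dict(_DEFAULTS[self.family])
        merged.update(self.param_ranges)
        self.param_ranges = merged

    def sample_params(self, rng: np.random.Generator) -> dict:
        out = {}
        for key, rngs in self.param_ranges.items():
            if key == "tint":
                out[key] = tuple(self._draw(lo, hi, rng) for lo, hi in rngs)
            else:
                lo, hi = rngs
                out[key] = self._draw(lo, hi, rng)
        return out

    def _draw(self, lo: float, hi: float, rng: np.random.Generator) -> float:
        mid = 0.5 * (lo + hi)
        return mid + self.jitter * (hi - lo) * (rng.random() - 0.5)


def _render(family: str, p: dict, h: int, w: int,
            rng: np.random.Generator) -> np.ndarray:
    """Render one float image in [0,1], shape (h, w, 3)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    tint = np.array(p["tint"])
    if family == "stripes":
        th = np.deg2rad(p["orientation"])
        phase = rng.random() * 2 * np.pi
        wave = np.sin(2 * np.pi * p["frequency"] * (xx * np.cos(th) + yy * np.sin(th)) + phase)
        lum = 1.0 - 0.5 * p["contrast"] * (wave + 1.0)
        img = lum[..., None] * tint
    elif family == "blobs":
        n_blobs = max(1, int(round(p["density"] * h * w)))
        field_ = np.zeros((h, w))
        for _ in range(n_blobs):
            cy, cx = rng.random() * h, rng.random() * w
            r = p["radius"] * (0.7 + 0.6 * rng.random())
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            field_ = np.maximum(field_, np.exp(-d2 / (2 * (r / 1.5) ** 2)))
        lum = 1.0 - p["darkness"] * field_
        img = lum[..., None] * tint
    elif family == "checker":
        cell = max(2.0, p["cell"])
        phase_y, phase_x = rng.random() * cell, rng.random() * cell
        pattern = (np.floor((yy + phase_y) / cell) + np.floor((xx + phase_x) / cell)) % 2
        lum = 1.0 - p["contrast"] * pattern
        img = lum[..., None] * tint
    elif family == "smooth_tint":
        th = rng.random() * 2 * np.pi
        ramp = (xx * np.cos(th) + yy * np.sin(th)) / max(h, w)
        ramp -= ramp.mean()
        lum = 1.0 + p["slope"] * ramp
        img = lum[..., None] * tint
    elif family == "noise":
        img = np.broadcast_to(tint, (h, w, 3)).copy()
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(family)
    noise_std = p.get("noise_std", 0.0)
    if noise_std > 0:
        img = img + rng.normal(0.0, noise_std, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_patch(spec: TextureClassSpec, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one (size, size, 3) uint8 patch from a class spec."""
    if size < 16:
        raise ValueError("patch size must be at least 16 pixels")
    p = spec.sample_params(rng)
    img = _render(spec.family, p, size, size, rng)
    return (img * 255).round().astype(np.uint8)


def generate_patch_dataset(specs: list[TextureClassSpec], n_per_class: int,
                           size: int, seed: int):
    """Balanced, seed-reproducible labelled patch dataset."""
    from .network import PatchDataset  # local import avoids a cycle

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for spec in specs:
        for _ in range(n_per_class):
            images.append(generate_patch(spec, size, rng))
            labels.append(spec.class_id)
    class_names = [f"C{spec.class_id}" for spec in specs]
    return PatchDataset(images=np.stack(images),
                        labels=np.array(labels, dtype=np.int64),
                        class_names=class_names)


# ---------------------------------------------------------------------------
# Presets


def easy_preset() -> list[TextureClassSpec]:
    """Six classes with disjoint parameter ranges and distinct tints."""
    return [
        TextureClassSpec(0, "stripes", {"orientation": (0.0, 15.0),
                                        "frequency": (0.15, 0.25)}),
        TextureClassSpec(1, "stripes", {"orientation": (75.0, 90.0),
                                        "frequency": (0.15, 0.25),
                                        "tint": ((0.4, 0.6), (0.7, 0.9), (0.6, 0.8))}),
        TextureClassSpec(2, "blobs", {}),
        TextureClassSpec(3, "checker", {}),
        TextureClassSpec(4, "smooth_tint", {}),
        TextureClassSpec(5, "noise", {}),
    ]


def hard_preset() -> list[TextureClassSpec]:
    """Four stripe classes sharing one tint; classes differ only in the
    joint orientation x frequency statistics, with overlapping marginal
    ranges (small interclass variability)."""
    tint = ((0.75, 0.9), (0.55, 0.7), (0.65, 0.8))  # one eosin-like palette
    return [
        TextureClassSpec(0, "stripes", {"orientation": (0.0, 35.0),
                                        "frequency": (0.06, 0.10), "tint": tint}),
        TextureClassSpec(1, "stripes", {"orientation": (0.0, 35.0),
                                        "frequency": (0.14, 0.20), "tint": tint}),
        TextureClassSpec(2, "stripes", {"orientation": (55.0, 90.0),
                                        "frequency": (0.06, 0.10), "tint": tint}),
        TextureClassSpec(3, "stripes", {"orientation": (55.0, 90.0),
                                        "frequency": (0.14, 0.20), "tint": tint}),
    ]


def blob_task(n_per_class: int, size: int, seed: int):
    """Two-class localization toy task: a single dark blob at a random
    location on a light field (class 0) vs. a uniform light field (class 1).

    Returns (dataset, bboxes) where bboxes[i] is the (r0, c0, r1, c1)
    half-open bounding box of the blob for class-0 patches (None for
    class-1 patches), aligned with dataset order.
    """
    from .network import PatchDataset

    rng = np.random.default_rng(seed)
    images, labels, bboxes = [], [], []
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_per_class):
        r = 4.0 + 2.0 * rng.random()
        cy = r + rng.random() * (size - 2 * r)
        cx = r + rng.random() * (size - 2 * r)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blob = np.exp(-d2 / (2 * (r / 1.5) ** 2))
        img = 0.85 - 0.6 * blob
        img = np.clip(img[..., None] + rng.normal(0, 0.03, (size, size, 3)), 0, 1)
        images.append((img * 255).round().astype(np.uint8))
        labels.append(0)
        pad = int(np.ceil(r)) + 2
        bboxes.append((max(0, int(cy) - pad), max(0, int(cx) - pad),
                       min(size, int(cy) + pad), min(size, int(cx) + pad)))
    for _ in range(n_per_class):
        img = np.clip(0.85 + rng.normal(0, 0.03, (size, size, 3)), 0, 1)
        images.append((img * 255).round().astype(np.uint8))
        labels.append(1)
        bboxes.append(None)
    ds = PatchDataset(images=np.stack(images),
                      labels=np.array(labels, dtype=np.int64),
                      class_names=["blob", "uniform"])
    return ds, bboxes


# ---------------------------------------------------------------------------
# Mosaic pseudo-slides


@dataclass
class MosaicLayout:
    """Canvas plus non-overlapping labelled regions.

    A region is ``(shape, class_id)`` where shape is either a rectangle
    ``(r0, c0, r1, c1)`` in half-open pixel coordinates or an (N, 2) array
    of polygon vertices in (row, col) order.
    """

    canvas_size: tuple[int, int]
    regions: list
    background_color: tuple[int, int, int] = (245, 245, 245)

    def region_masks(self) -> list[tuple[np.ndarray, int]]:
        from skimage.draw import polygon as sk_polygon

        H, W = self.canvas_size
        out = []
        for shape, class_id in self.regions:
            mask = np.zeros((H, W), dtype=bool)
            arr = np.asarray(shape)
            if arr.ndim == 1 and arr.size == 4:
                r0, c0, r1, c1 = (int(v) for v in arr)
                if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
                    raise ValueError(f"rectangle {shape} outside canvas {self.canvas_size}")
                mask[r0:r1, c0:c1] = True
            elif arr.ndim == 2 and arr.shape[1] == 2:
                rr, cc = sk_polygon(arr[:, 0], arr[:, 1], shape=(H, W))
                mask[rr, cc] = True
            else:
                raise ValueError(f"region shape {shape!r} is neither a rectangle "
                                 "nor a polygon vertex array")
            out.append((mask, int(class_id)))
        return out

    def label_map(self) -> np.ndarray:
        H, W = self.canvas_size
        lm = np.full((H, W), BACKGROUND_LABEL, dtype=np.int64)
        painted = np.zeros((H, W), dtype=bool)
        for mask, class_id in self.region_masks():
            if np.any(painted & mask):
                raise ValueError("mosaic regions overlap")
            lm[mask] = class_id
            painted |= mask
        return lm


def generate_mosaic_slide(layout: MosaicLayout,
                          specs: list[TextureClassSpec], seed: int):
    """Render a mosaic slide and its ground-truth label map.

    Background is the near-white layout colour with small Gaussian noise;
    each region is filled with a fresh draw from its class's texture spec.
    Returns (slide uint8 HxWx3, label_map int64 HxW with background = -1).
    """
    spec_by_id = {s.class_id: s for s in specs}
    for _, class_id in layout.regions:
        if int(class_id) not in spec_by_id:
            raise ValueError(f"no texture spec for region class {class_id}")
    rng = np.random.default_rng(seed)
    H, W = layout.canvas_size
    bg = np.array(layout.background_color, dtype=float) / 255.0
    slide = np.clip(bg + rng.normal(0, 0.012, size=(H, W, 3)), 0, 1)
    label_map = layout.label_map()
    for mask, class_id in layout.region_masks():
        spec = spec_by_id[class_id]
        p = spec.sample_params(rng)
        rows = np.where(mask.any(axis=1))[0]
        cols = np.where(mask.any(axis=0))[0]
        r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
        tex = _render(spec.family, p, r1 - r0, c1 - c0, rng)
        sub = mask[r0:r1, c0:c1]
        region_view = slide[r0:r1, c0:c1]
        region_view[sub] = tex[sub]
    return (slide * 255).round().astype(np.uint8), label_map


def quadrant_mosaic_layout(canvas: int = 1024, margin: int = 32,
                           n_classes: int = 4) -> MosaicLayout:
    """Four equal textured quadrants inset by ``margin`` from the canvas
    edge; region edges fall on multiples of ``margin`` so integer-factor
    tissue masks align exactly."""
    mid = canvas // 2
    rects = [
        ((margin, margin, mid, mid), 0),
        ((margin, mid, mid, canvas - margin), 1 % n_classes),
        ((mid, margin, canvas - margin, mid), 2 % n_classes),
        ((mid, mid, canvas - margin, canvas - margin), 3 % n_classes),
    ]
    return MosaicLayout(canvas_size=(canvas, canvas), regions=rects)


class OracleTileClassifier:
    """Ground-truth tile classifier for pipeline tests: returns a one-hot
    probability row at the majority non-background label inside each tile's
    footprint.  Conforms to the coordinate-aware classifier protocol of
    :func:`tissuegrid.wsi.classify_tiles`."""

    def __init__(self, label_map: np.ndarray, n_classes: int):
        self.label_map = np.asarray(label_map)
        self.n_classes = int(n_classes)

    def __call__(self, tiles: np.ndarray, coords) -> np.ndarray:
        t = tiles.shape[1]
        probs = np.zeros((len(coords), self.n_classes))
        for i, (r, c) in enumerate(coords):
            footprint = self.label_map[r : r + t, c : c + t]
            tissue = footprint[footprint != BACKGROUND_LABEL]
            if tissue.size == 0:
                probs[i] = 1.0 / self.n_classes
            else:
                probs[i, np.bincount(tissue).argmax()] = 1.0
        return probs


def orientation_statistic(img: np.ndarray) -> float:
    """Signed gradient-anisotropy statistic in [-1, 1]: positive when
    intensity varies mostly along columns (vertical stripe pattern,
    orientation near 0 deg), negative when it varies mostly along rows."""
    g = np.asarray(img, dtype=float).mean(axis=2)
    gy, gx = np.gradient(g)
    ex, ey = np.abs(gx).mean(), np.abs(gy).mean()
    return float((ex - ey) / (ex + ey + 1e-12))
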