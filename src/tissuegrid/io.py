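"""Disk formats: directory-per-class PNG patch datasets (or a manifest
CSV), palette-indexed label-map PNGs with a JSON legend, per-tile CSV
reports, and slide images."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .common import BACKGROUND_LABEL
from .network import PatchDataset
from .wsi import SegmentationMap, TileGrid

__all__ = [
    "save_patch_dataset",
    "load_patch_dataset",
    "load_manifest_dataset",
    "save_label_map",
    "load_label_map",
    "save_tile_csv",
    "read_slide",
    "write_image",
    "default_palette",
]


def save_patch_dataset(ds: PatchDataset, root) -> None:
    root = Path(root)
    for name in ds.class_names:
        (root / name).mkdir(parents=True, exist_ok=True)
    counters = [0] * len(ds.class_names)
    for img, label in zip(ds.images, ds.labels):
        name = ds.class_names[label]
        iio.imwrite(root / name / f"{name}_{counters[label]:05d}.png", img)
        counters[label] += 1


def load_patch_dataset(root) -> PatchDataset:
    """Directory-per-class layout; class order is sorted directory name."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    images, labels = [], []
    for label, d in enumerate(class_dirs):
        for f in sorted(d.glob("*.png")):
            images.append(iio.imread(f))
            labels.append(label)
    return PatchDataset(np.stack(images), np.array(labels),
                        [d.name for d in class_dirs])


def load_manifest_dataset(csv_path, class_names=None) -> PatchDataset:
    """Manifest CSV with columns (path, label); paths relative to the CSV."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    images = [iio.imread(csv_path.parent / p) for p in df["path"]]
    labels = df["label"].to_numpy()
    if class_names is None:
        class_names = [f"C{i}" for i in range(int(labels.max()) + 1)]
    return PatchDataset(np.stack(images), labels, class_names)


def default_palette(n_classes: int) -> dict[int, tuple[int, int, int]]:
    """Deterministic, well-separated class colours (tab10-like cycle)."""
    base = [(31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
            (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
            (188, 189, 34), (23, 190, 207)]
    return {i: base[i % len(base)] for i in range(n_classes)}


def save_label_map(label_map: np.ndarray, png_path, legend_path,
                   palette: dict[int, tuple[int, int, int]],
                   class_names: list[str] | None = None) -> None:
    """Palette-indexed PNG (index 0 = background, class c at index c+1)
    plus a JSON legend mapping indices to class ids, names, and colours."""
    lm = np.asarray(label_map)
    idx = (lm + 1).astype(np.uint8)  # background -1 -> 0
    pal = [255, 255, 255]
    legend = {0: {"class_id": BACKGROUND_LABEL, "name": "background",
                  "rgb": [255, 255, 255]}}
    n = int(lm.max()) + 1 if lm.max() >= 0 else 0
    for c in range(n):
        rgb = list(palette.get(c, (0, 0, 0)))
        pal.extend(rgb)
        name = class_names[c] if class_names else f"C{c}"
        legend[c + 1] = {"class_id": c, "name": name, "rgb": rgb}
    img = Image.fromarray(idx, mode="P")
    img.putpalette(pal + [0] * (768 - len(pal)))
    img.save(png_path)
    Path(legend_path).write_text(json.dumps(legend, indent=2))


def load_label_map(png_path) -> np.ndarray:
    idx = np.asarray(Image.open(png_path)).astype(np.int64)
    return idx - 1


def save_tile_csv(grid: TileGrid, probs: np.ndarray, path,
                  class_names: list[str] | None = None) -> None:
    probs = np.asarray(probs)
    names = class_names or [f"C{i}" for i in range(probs.shape[1])]
    df = pd.DataFrame(grid.coords, columns=["row", "col"])
    df["class"] = [names[i] for i in probs.argmax(axis=1)] if len(df) else []
    for j, name in enumerate(names):
        df[f"p_{name}"] = probs[:, j] if len(df) else []
    df.to_csv(path, index=False)


def read_slide(path) -> np.ndarray:
    """Plain PNG/TIFF slide as an HxWx3 uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def write_image(img: np.ndarray, path) -> None:
    iio.imwrite(path, img)


def segmentation_outputs(seg: SegmentationMap, grid: TileGrid,
                         probs: np.ndarray, slide: np.ndarray, out_dir,
                         class_names: list[str] | None = None,
                         alpha: float = 0.5) -> None:
    """Write the standard segmentation artifacts: label map PNG + legend,
    per-tile CSV, and the colour overlay."""
    from .wsi import render_overlay

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = int(seg.label_map.max()) + 1 if seg.label_map.max() >= 0 else 1
    pal = default_palette(max(n, probs.shape[1] if probs.size else n))
    save_label_map(seg.label_map, out / "label_map.png", out / "legend.json",
                   pal, class_names)
    save_tile_csv(grid, probs, out / "tiles.csv", class_names)
    write_image(render_overlay(seg, slide, pal, alpha), out / "overlay.png")
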