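"""Pinned desk-scale benchmarks.

These functions fix the study conditions — generator presets, sample
sizes, seeds, epochs — used by the test suite, the acceptance script, and
the examples, so every consumer runs the identical configuration.

* easy benchmark: 6-class easy texture preset, 300 patches/class at 32 px,
  seed 7, 15 epochs, default augmentation (rotations/flips are
  label-preserving for these classes).
* ablation benchmark: 4-class hard preset (shared tint; classes defined by
  the joint orientation x frequency statistics), 150 patches/class, 30
  epochs, 3 seeds, geometric augmentation off (90-degree rotations and
  flips would change the orientation-defined labels).
* mosaic benchmark: 1024 x 1024 pseudo-slide with four 480 x 480 textured
  quadrants on a near-white background; tissue mask IoU plus end-to-end
  oracle-classifier segmentation agreement on interior tissue.
* blob Grad-CAM benchmark: blob-vs-uniform toy task; fraction of held-out
  blob patches whose mean heat inside the blob bounding box exceeds the
  mean heat outside.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_cdt

from .common import BACKGROUND_LABEL
from .gradcam import gradcam
from .network import (
    AugmentFlags, ModelConfig, TrainConfig, build_classifier,
    stratified_split, train_classifier,
)
from .synthetic import (
    OracleTileClassifier, blob_task, easy_preset, generate_mosaic_slide,
    generate_patch_dataset, hard_preset, quadrant_mosaic_layout,
)
from .wsi import compute_tissue_mask, classify_tiles, enumerate_tiles, \
    stitch_segmentation

__all__ = [
    "run_easy_benchmark",
    "run_ablation_benchmark",
    "run_mosaic_benchmark",
    "run_blob_gradcam_benchmark",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = {
    "full": (True, True),            # bilinear + attention
    "bilinear_only": (True, False),
    "attention_only": (False, True),
    "plain": (False, False),         # bare backbone + dense head
}


def run_easy_benchmark(seed: int = 7, n_per_class: int = 300,
                       epochs: int = 15, size: int = 32):
    """Train the full model on the pinned easy 6-class set; returns
    (model, history, held-out accuracy)."""
    ds = generate_patch_dataset(easy_preset(), n_per_class, size, seed=seed)
    train, val = stratified_split(ds, 0.2, seed=seed)
    cfg = ModelConfig(n_classes=len(ds.class_names), input_size=size)
    model = build_classifier(cfg, seed=seed, class_names=ds.class_names)
    model, history = train_classifier(model, train, val,
                                      TrainConfig(epochs=epochs, seed=seed))
    return model, history, history["val_acc"][-1]


def run_ablation_benchmark(seeds=(0, 1, 2), n_per_class: int = 150,
                           epochs: int = 30, size: int = 32,
                           variants=None) -> dict[str, float]:
    """Mean held-out accuracy per model variant on the pinned hard preset."""
    specs = hard_preset()
    flags = AugmentFlags(rotate90s=False, hflip=False)  # labels are
    # orientation-defined; geometric augmentation would not preserve them
    out = {}
    for name, (use_bil, use_att) in (variants or ABLATION_VARIANTS).items():
        accs = []
        for seed in seeds:
            ds = generate_patch_dataset(specs, n_per_class, size,
                                        seed=100 + seed)
            train, val = stratified_split(ds, 0.2, seed=seed)
            cfg = ModelConfig(n_classes=len(ds.class_names), input_size=size,
                              use_bilinear=use_bil, use_attention=use_att)
            model = build_classifier(cfg, seed=seed,
                                     class_names=ds.class_names)
            _, hist = train_classifier(
                model, train, val,
                TrainConfig(epochs=epochs, seed=seed, augment=flags))
            accs.append(hist["val_acc"][-1])
        out[name] = float(np.mean(accs))
    return out


def run_mosaic_benchmark(seed: int = 0, canvas: int = 1024,
                         downsample: int = 32, tile_size: int = 224,
                         stride: int = 128):
    """End-to-end stage-2 pipeline on the pinned mosaic with the
    ground-truth oracle classifier.

    Returns a dict with the tissue-mask IoU against the true non-background
    region and the label agreement on interior tissue pixels (further than
    ``tile_size`` from any region boundary, Chebyshev distance).
    """
    specs = easy_preset()[:4]
    layout = quadrant_mosaic_layout(canvas, margin=downsample, n_classes=4)
    slide, truth = generate_mosaic_slide(layout, specs, seed=seed)

    mask = compute_tissue_mask(slide, downsample=downsample)
    tissue_true = truth != BACKGROUND_LABEL
    tissue_pred = mask.at_full_resolution(truth.shape).astype(bool)
    inter = np.logical_and(tissue_true, tissue_pred).sum()
    union = np.logical_or(tissue_true, tissue_pred).sum()
    iou = inter / union if union else 1.0

    grid = enumerate_tiles(mask, truth.shape, tile_size, stride, 0.5)
    oracle = OracleTileClassifier(truth, n_classes=4)
    probs = classify_tiles(oracle, slide, grid)
    seg = stitch_segmentation(grid, probs, truth.shape)

    interior = np.zeros_like(tissue_true)
    for c in np.unique(truth[tissue_true]):
        region = truth == c
        dist = distance_transform_cdt(region, metric="chessboard")
        interior |= dist > tile_size
    agree = (seg.label_map[interior] == truth[interior]).mean() \
        if interior.any() else 1.0
    return {
        "mask_iou": float(iou),
        "interior_agreement": float(agree),
        "n_tiles": len(grid.coords),
        "n_interior_pixels": int(interior.sum()),
        "segmentation": seg,
        "truth": truth,
    }


def run_blob_gradcam_benchmark(seed: int = 3, n_per_class: int = 150,
                               n_eval: int = 50, epochs: int = 40,
                               size: int = 32):
    """Train the blob-vs-uniform toy model, then score Grad-CAM
    localization: the fraction of held-out blob patches whose mean heat
    inside the blob bounding box exceeds the mean heat outside."""
    ds, bboxes = blob_task(n_per_class + n_eval, size, seed=seed)
    n_tot = n_per_class + n_eval
    # blob patches come first, uniform second; hold out the last n_eval blobs
    train_idx = np.r_[0:n_per_class, n_tot : n_tot + n_per_class]
    eval_idx = np.arange(n_per_class, n_tot)
    train_ds = ds.subset(train_idx)
    tr, val = stratified_split(train_ds, 0.2, seed=seed)
    cfg = ModelConfig(n_classes=2, input_size=size)
    model = build_classifier(cfg, seed=seed, class_names=ds.class_names)
    model, hist = train_classifier(model, tr, val,
                                   TrainConfig(epochs=epochs, seed=seed))
    hits = 0
    for i in eval_idx:
        heat = gradcam(model, ds.images[i], target_class=0)
        r0, c0, r1, c1 = bboxes[i]
        inside = np.zeros(heat.values.shape, dtype=bool)
        inside[r0:r1, c0:c1] = True
        if heat.values[inside].mean() > heat.values[~inside].mean():
            hits += 1
    return {
        "model": model,
        "val_acc": hist["val_acc"][-1],
        "localization_fraction": hits / len(eval_idx),
        "n_eval": len(eval_idx),
    }
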