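"""Synthetic study data: texture patch datasets and mosaic pseudo-slides.

Generates the easy (disjoint-range) and hard (adjacent-range, shared tint)
presets, prints the statistics that make the hard preset hard for
first-order classifiers, and renders a mosaic slide with its ground-truth
label map.
"""

import numpy as np

import tissuegrid as tg
from tissuegrid.synthetic import orientation_statistic

easy = tg.generate_patch_dataset(tg.easy_preset(), 20, 32, seed=1)
hard = tg.generate_patch_dataset(tg.hard_preset(), 20, 32, seed=1)
print(f"easy preset: {len(easy)} patches, {len(easy.class_names)} classes")
print(f"hard preset: {len(hard)} patches, {len(hard.class_names)} classes")

# Mean per-channel colour by class: the easy classes separate on tint, the
# hard classes share one palette (so colour alone cannot classify them).
for name, ds in (("easy", easy), ("hard", hard)):
    means = [ds.images[ds.labels == c].mean() for c in range(len(ds.class_names))]
    print(f"{name} per-class mean intensity: {np.round(means, 1)}")

# The hard classes differ in joint orientation x frequency structure:
for c in range(4):
    stats = [orientation_statistic(img) for img in hard.images[hard.labels == c]]
    print(f"hard class {c}: gradient-anisotropy mean {np.mean(stats):+.3f}")
# positive = near-horizontal stripes, negative = near-vertical.

# A mosaic pseudo-slide with four textured quadrants on near-white background.
layout = tg.quadrant_mosaic_layout(canvas=512, margin=32)
slide, truth = tg.generate_mosaic_slide(layout, tg.easy_preset()[:4], seed=2)
bg_frac = (truth == tg.BACKGROUND_LABEL).mean()
print(f"\nmosaic: slide {slide.shape}, background fraction {bg_frac:.4f}")
print(f"tissue classes present: {sorted(set(truth[truth >= 0]))}")
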