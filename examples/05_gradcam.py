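"""Grad-CAM explanation of patch predictions on the blob-vs-uniform toy
task: after training, the heat should concentrate on the blob, the only
discriminative structure in the image.
"""

import numpy as np

import tissuegrid as tg
from tissuegrid import benchmarks as bm

res = bm.run_blob_gradcam_benchmark(seed=3)
model = res["model"]
print(f"blob-vs-uniform model: held-out accuracy {res['val_acc']:.3f}")
print(f"heat localizes inside the blob bounding box on "
      f"{100 * res['localization_fraction']:.0f}% of {res['n_eval']} "
      f"held-out blob patches")

# Inspect one patch in detail.
ds, bboxes = tg.blob_task(5, 32, seed=11)
img, (r0, c0, r1, c1) = ds.images[0], bboxes[0]
heat = tg.gradcam(model, img, target_class=0)
inside = np.zeros(heat.values.shape, dtype=bool)
inside[r0:r1, c0:c1] = True
print(f"\nexample patch, blob bbox rows {r0}-{r1} cols {c0}-{c1} "
      f"(hooked layer: {heat.layer_name})")
print(f"mean heat inside bbox:  {heat.values[inside].mean():.3f}")
print(f"mean heat outside bbox: {heat.values[~inside].mean():.3f}")
blend = tg.blend_heatmap(img, heat, alpha=0.5)
print(f"jet-colormap blend: {blend.shape} uint8 image")
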