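"""Grad-CAM visual explanations.

For a target class, channel weights are the spatial means of the gradient
of the class *logit* (pre-softmax score) with respect to the hooked
convolutional layer's activations; the heatmap is the ReLU of the
weight-summed activations, min-max normalized to [0, 1] and bilinearly
upsampled to the input resolution.  By default the hook attaches to the
final convolutional block of the backbone; the bilinear and attention
modules are treated as part of the classification head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .network import TissueClassifier

__all__ = ["Heatmap", "gradcam", "blend_heatmap"]


@dataclass
class Heatmap:
    """Upsampled class-activation map in [0, 1] (max 1 unless the raw map
    is identically zero, then all zeros)."""

    values: np.ndarray
    target_class: int
    layer_name: str


def gradcam(model: TissueClassifier, img: np.ndarray, target_class: int,
            layer: str | None = None) -> Heatmap:
    img = np.asarray(img)
    s = model.config.input_size
    if img.shape[:2] != (s, s):
        raise ValueError(f"image is {img.shape[:2]}, model expects ({s}, {s})")
    if not (0 <= target_class < model.config.n_classes):
        raise ValueError(f"target_class {target_class} out of range")
    layer = layer or model.last_conv_layer()
    names = [n for n, _ in model.net.layers]
    if layer not in names:
        raise ValueError(f"unknown layer {layer!r}; available: {names}")

    x = model.preprocess(img[None] if img.ndim == 3 else img)
    logits, act = model.net.forward(x, train=False, capture=layer)
    if act is None or act.ndim != 4:
        raise ValueError(f"layer {layer!r} does not produce spatial activations")
    g = np.zeros_like(logits)
    g[0, target_class] = 1.0
    _, grad = model.net.backward(g, capture=layer)

    weights = grad[0].mean(axis=(1, 2))               # one weight per channel
    cam = np.maximum((weights[:, None, None] * act[0]).sum(axis=0), 0.0)
    values = resize(cam, (s, s), order=1, mode="edge", anti_aliasing=False)
    values = np.maximum(values, 0.0)
    if values.max() > 0:                 # min-max normalize after upsampling
        values = values / values.max()
    return Heatmap(values=values, target_class=int(target_class), layer_name=layer)


def blend_heatmap(img: np.ndarray, heat: Heatmap, alpha: float = 0.5) -> np.ndarray:
    """Jet-colormap blend of a heatmap over its source patch (uint8 RGB)."""
    from matplotlib import colormaps

    base = np.asarray(img, dtype=float)
    if img.dtype == np.uint8:
        base = base / 255.0
    color = colormaps["jet"](heat.values)[..., :3]
    out = (1 - alpha) * base + alpha * color
    return (np.clip(out, 0, 1) * 255).round().astype(np.uint8)
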