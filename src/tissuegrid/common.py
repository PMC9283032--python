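"""Shared constants and small validation helpers."""

import numpy as np

# Reserved label for non-tissue pixels in ground-truth and stitched label maps.
BACKGROUND_LABEL = -1


def check_rgb_image(img, name: str = "image") -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must be an HxWx3 RGB array, got shape {arr.shape}")
    return arr
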