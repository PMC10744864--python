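"""Grad-CAM heatmaps for the patch classifier.

Gradient-weighted class activation mapping: the gradient of the target-class
logit is taken with respect to the post-activation feature maps of the last
convolutional layer, globally average-pooled per channel into weights, and
the rectified weighted sum of the feature maps forms the localization map.
The map is bilinearly upsampled to patch resolution and max-normalized for
display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from octmargin.cnn.model import PatchCNN
from octmargin.cnn.train import normalize_patch_array

__all__ = ["HeatmapOverlay", "gradcam"]


@dataclass
class HeatmapOverlay:
    raw_map: np.ndarray        # (h', w') non-negative, last-conv resolution
    upsampled_map: np.ndarray  # (H, W) in [0, 1], max = 1 unless raw_map == 0
    overlay: np.ndarray        # (H, W, 3) RGB in [0, 1]


def gradcam(
    model: PatchCNN,
    patch: np.ndarray,
    target_class: int = 1,
    colormap: str = "jet",
    alpha: float = 0.4,
) -> HeatmapOverlay:
    """Grad-CAM heatmap of one patch for the given class.

    ``patch`` is a (H, W) grayscale array matching the model input shape
    (integer dtypes are scaled to [0, 1]). Deterministic: identical
    checkpoint and patch give identical heatmaps.
    """
    h, w, c = model.arch.input_shape
    patch = np.asarray(patch)
    if patch.shape != (h, w):
        raise ValueError(f"patch shape {patch.shape} does not match model input {(h, w)}")
    x = patch.astype(np.float32)
    if np.issubdtype(patch.dtype, np.integer):
        x /= np.iinfo(patch.dtype).max
    # model inputs are standardized per patch; the overlay keeps [0, 1]
    x_in = normalize_patch_array(x[None, :, :])[0]

    act, grad = model.last_conv_activation_and_grad(x_in[None, :, :, None], target_class)
    act, grad = act[0], grad[0]                   # (h', w', channels)
    weights = grad.mean(axis=(0, 1))              # global-average-pooled gradients
    raw = np.maximum((act * weights).sum(axis=2), 0.0).astype(np.float64)

    up = resize(raw, (h, w), order=1, anti_aliasing=False)
    up = np.clip(up, 0.0, None)
    if up.max() > 0:
        up = up / up.max()

    cmap = colormaps[colormap]
    overlay = (1.0 - alpha) * np.repeat(x.astype(np.float64)[:, :, None], 3, axis=2)
    overlay += alpha * cmap(up)[:, :, :3]
    return HeatmapOverlay(raw_map=raw, upsampled_map=up, overlay=np.clip(overlay, 0, 1))
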