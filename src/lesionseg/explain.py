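"""Grad-CAM attention maps for the segmentation network.

For a dense sigmoid output the classification-style Grad-CAM objective does
not directly apply; here the scalar objective is the mean pre-sigmoid logit
over the predicted-foreground pixels (over all pixels when the prediction is
empty).  Channel weights are the spatial means of the objective's gradient
at the target layer, the raw map is the ReLU of the weighted activation sum,
bilinearly upsampled to input resolution and min-max normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from . import nn
from .core import SlicePair
from .model import DualAttentionASPPUNet

__all__ = ["CamResult", "gradcam", "overlay"]


@dataclass
class CamResult:
    heatmap: np.ndarray          # [0, 1] at input resolution (all zeros if degenerate)
    target_layer: str
    overlay: np.ndarray | None = None


def gradcam(model: DualAttentionASPPUNet, sl: SlicePair | np.ndarray,
            target_layer: str = "aspp_out", threshold: float = 0.5) -> CamResult:
    image = sl.image if isinstance(sl, SlicePair) else np.asarray(sl)
    prob = model.forward(image, training=False, capture=True)
    if target_layer not in model.captured:
        raise KeyError(
            f"unknown target layer {target_layer!r}; available: "
            f"{sorted(model.captured)}"
        )
    target = model.captured[target_layer]
    if target.data.ndim != 4 or target.data.shape[1] < 2 or target.data.shape[2] < 2:
        raise ValueError(f"target layer {target_layer!r} has no usable spatial extent")
    logits = model.captured["logits"]
    fg = prob.data >= threshold
    if not fg.any():
        fg = np.ones_like(prob.data, dtype=bool)
    objective = nn.masked_mean(logits, fg)
    objective.backward()
    grad = target.grad
    if grad is None:
        grad = np.zeros_like(target.data)
    weights = grad.mean(axis=(1, 2), keepdims=True)            # (N,1,1,C)
    raw = np.maximum((weights * target.data).sum(axis=-1), 0.0)[0]
    cam = transform.resize(raw, image.shape, order=1, preserve_range=True,
                           anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        lo = cam.min()
        cam = (cam - lo) / (peak - lo) if peak > lo else np.zeros_like(cam)
    else:
        cam = np.zeros_like(cam)
    return CamResult(heatmap=cam, target_layer=target_layer)


def overlay(cam: CamResult | np.ndarray, image: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the colormapped heatmap onto the grayscale image.

    Returns an (H, W, 3) float array in [0, 1]:
    (1 - alpha) * gray + alpha * colormap(heatmap).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    heat = cam.heatmap if isinstance(cam, CamResult) else np.asarray(cam)
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    gray_rgb = np.stack([gray] * 3, axis=-1)
    from matplotlib import colormaps
    heat_rgb = colormaps[cmap](heat)[..., :3]
    blended = (1.0 - alpha) * gray_rgb + alpha * heat_rgb
    if isinstance(cam, CamResult):
        cam.overlay = blended
    return blended
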