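"""Geometric training-set augmentation applied identically to image and mask.

Rotations (45, 90, 125 degrees), scalings (1.5, 2) and a horizontal
translation, each producing one extra sample per input slice: the default
spec expands a training set 7-fold (original + 3 + 2 + 1).  Images are
interpolated bilinearly, masks with nearest neighbor and re-binarized, so the
co-transform contract (same geometric parameters for both channels) holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from .core import SlicePair

__all__ = ["AugmentSpec", "rotate_pair", "scale_pair", "translate_pair",
           "augment_dataset"]


@dataclass
class AugmentSpec:
    rotation_angles: tuple[float, ...] = (45.0, 90.0, 125.0)
    scale_factors: tuple[float, ...] = (1.5, 2.0)
    translate_dx: float | None = None   # None -> 0.1 x image width
    fill_value: float = 0.0

    def __post_init__(self):
        if any(abs(a) >= 360 for a in self.rotation_angles):
            raise ValueError("rotation angles must lie in (-360, 360)")
        if any(f <= 0 for f in self.scale_factors):
            raise ValueError("scale factors must be positive")


def _with(sl: SlicePair, image, mask, tag: str) -> SlicePair:
    return SlicePair(image=image, mask=(np.asarray(mask) > 0.5).astype(np.uint8),
                     patient_id=sl.patient_id, slice_index=sl.slice_index,
                     tag=tag, n_slices=sl.n_slices)


def rotate_pair(sl: SlicePair, angle: float, fill_value: float = 0.0) -> SlicePair:
    """Rotate counterclockwise about the image center ((H-1)/2, (W-1)/2);
    out-of-frame regions take ``fill_value``; shape is preserved."""
    if angle % 360 == 0:
        return _with(sl, sl.image.copy(), sl.mask.copy(), f"rot{angle:g}")
    img = transform.rotate(sl.image, angle, resize=False, order=1,
                           preserve_range=True, cval=fill_value)
    msk = transform.rotate(sl.mask.astype(np.float64), angle, resize=False, order=0,
                           preserve_range=True, cval=0.0)
    return _with(sl, img, msk, f"rot{angle:g}")


def scale_pair(sl: SlicePair, factor: float, fill_value: float = 0.0) -> SlicePair:
    """Zoom about the center by ``factor``, then center-crop (factor > 1) or
    center-pad (factor < 1) back to the original shape."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1:
        return _with(sl, sl.image.copy(), sl.mask.copy(), f"scale{factor:g}")
    H, W = sl.image.shape
    img = transform.rescale(sl.image, factor, order=1, preserve_range=True,
                            anti_aliasing=False)
    msk = transform.rescale(sl.mask.astype(np.float64), factor, order=0,
                            preserve_range=True, anti_aliasing=False)

    def refit(arr, fill):
        h, w = arr.shape
        if h >= H:
            top, left = (h - H) // 2, (w - W) // 2
            return arr[top:top + H, left:left + W]
        out = np.full((H, W), fill, dtype=arr.dtype)
        top, left = (H - h) // 2, (W - w) // 2
        out[top:top + h, left:left + w] = arr
        return out

    return _with(sl, refit(img, fill_value), refit(msk, 0.0), f"scale{factor:g}")


def translate_pair(sl: SlicePair, dx: int, fill_value: float = 0.0) -> SlicePair:
    """Shift both channels horizontally by ``dx`` pixels (positive = right);
    vacated columns take ``fill_value``."""
    H, W = sl.image.shape
    dx = int(dx)
    if abs(dx) >= W:
        raise ValueError(f"|dx| = {abs(dx)} must be smaller than width {W}")
    img = np.full_like(sl.image, fill_value)
    msk = np.zeros_like(sl.mask)
    if dx >= 0:
        img[:, dx:] = sl.image[:, :W - dx]
        msk[:, dx:] = sl.mask[:, :W - dx]
    else:
        img[:, :W + dx] = sl.image[:, -dx:]
        msk[:, :W + dx] = sl.mask[:, -dx:]
    return _with(sl, img, msk, f"tx{dx:+d}")


def augment_dataset(slices: list[SlicePair], spec: AugmentSpec | None = None
                    ) -> list[SlicePair]:
    """Originals plus one output per listed transform parameter."""
    spec = spec or AugmentSpec()
    out: list[SlicePair] = []
    for sl in slices:
        out.append(sl)
        for angle in spec.rotation_angles:
            out.append(rotate_pair(sl, angle, spec.fill_value))
        for factor in spec.scale_factors:
            out.append(scale_pair(sl, factor, spec.fill_value))
        dx = spec.translate_dx
        if dx is None:
            dx = 0.1 * sl.image.shape[1]
        out.append(translate_pair(sl, int(round(dx)), spec.fill_value))
    return out
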