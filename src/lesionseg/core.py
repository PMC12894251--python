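"""Shared domain containers for volumes, slices, and predictions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumePair", "SlicePair", "Prediction", "as_binary"]


def as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate and return a {0,1} uint8 copy of a binary array."""
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary, found values {vals[:10]}")
    return arr.astype(np.uint8)


@dataclass
class VolumePair:
    """A 3D intensity volume with its aligned binary lesion mask.

    Axis 0 is the axial stacking axis (inferior to superior) after loading.
    """

    intensity: np.ndarray
    mask: np.ndarray
    patient_id: str
    orientation: str = "SPL-canonical"
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.mask = as_binary(self.mask)
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class SlicePair:
    """One 2D axial image with its mask, tagged for leakage-safe splitting."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    slice_index: int
    tag: str = "orig"
    n_slices: int | None = None   # depth of the source volume, if known

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = as_binary(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class Prediction:
    """Sigmoid probability map and its thresholded binary mask."""

    probabilities: np.ndarray
    threshold: float = 0.5
    binary_mask: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.binary_mask = (self.probabilities >= self.threshold).astype(np.uint8)
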