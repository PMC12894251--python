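"""Volume loading and the 2D slice preparation pipeline.

Stages: NIfTI ingestion with canonical reorientation, axial slicing, slice
retention (central band + minimum lesion size), skull stripping (contrast
stretch, histogram equalization, Otsu threshold, morphological opening and
closing, largest component, hole filling), NL-means denoising, bias-field
correction (log-domain polynomial fit, or delegated N4), resizing, and
min-max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, filters, morphology, transform

from .core import SlicePair, VolumePair

__all__ = [
    "SliceFilterConfig",
    "PreprocessConfig",
    "load_volume_pair",
    "slice_axial",
    "select_slices",
    "skull_strip",
    "denoise_nlmeans",
    "bias_correct",
    "resize_pair",
    "preprocess_volume",
    "write_slices",
]


@dataclass
class SliceFilterConfig:
    """Retention rule: keep the central band of axial slices, then keep
    slices whose lesion mask has at least ``min_lesion_pixels`` foreground
    pixels."""

    min_lesion_pixels: int = 5
    central_band_fraction: float = 0.70
    per_component: bool = False  # alternative reading: largest component size

    def __post_init__(self):
        if self.min_lesion_pixels < 0:
            raise ValueError("min_lesion_pixels must be >= 0")
        if not 0 < self.central_band_fraction <= 1:
            raise ValueError("central_band_fraction must lie in (0, 1]")


@dataclass
class PreprocessConfig:
    target_size: tuple[int, int] = (256, 256)
    denoise: str = "nlmeans"              # none | nlmeans
    nlmeans_patch_size: int = 3
    nlmeans_search_window: int = 11
    nlmeans_filter_strength: float | None = None  # None -> 0.8 x estimated sigma
    bias_correction: str = "polynomial"   # none | polynomial | delegated_n4
    bias_poly_degree: int = 2
    skull_strip: bool = True
    morphology_radius: int = 2
    normalize: str = "minmax"             # none | minmax

    def __post_init__(self):
        if min(self.target_size) <= 0:
            raise ValueError("target_size must be positive")
        if self.nlmeans_patch_size % 2 == 0:
            raise ValueError("nlmeans_patch_size must be odd")
        if self.nlmeans_search_window < self.nlmeans_patch_size:
            raise ValueError("search window must be >= patch size")


def load_volume_pair(image_path, mask_path, patient_id: str) -> VolumePair:
    """Load an image/mask NIfTI pair, reorient to canonical axes with axis 0
    stacking axially (inferior to superior), and binarize the mask at > 0."""
    img = nib.as_closest_canonical(nib.load(str(image_path)))
    msk = nib.as_closest_canonical(nib.load(str(mask_path)))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    mask = np.asarray(msk.get_fdata())
    if data.shape != mask.shape:
        raise ValueError(
            f"image shape {data.shape} does not match mask shape {mask.shape}"
        )
    # canonical RAS order is (x, y, z); move the superior axis first
    data = np.transpose(data, (2, 1, 0))
    mask = np.transpose(mask, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    return VolumePair(intensity=data, mask=(mask > 0).astype(np.uint8),
                      patient_id=patient_id,
                      voxel_spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])))


def slice_axial(vol: VolumePair) -> list[SlicePair]:
    """One SlicePair per plane along axis 0, order preserved."""
    depth = vol.intensity.shape[0]
    return [
        SlicePair(image=vol.intensity[k], mask=vol.mask[k],
                  patient_id=vol.patient_id, slice_index=k, n_slices=depth)
        for k in range(depth)
    ]


def _lesion_pixels(mask: np.ndarray, per_component: bool) -> int:
    if not per_component:
        return int(mask.sum())
    if mask.sum() == 0:
        return 0
    labels, n = ndimage.label(mask)
    return int(max(np.bincount(labels.ravel())[1:]))


def select_slices(slices: list[SlicePair], cfg: SliceFilterConfig | None = None
                  ) -> list[SlicePair]:
    """Apply the central-band restriction, then the minimum-lesion-size rule."""
    cfg = cfg or SliceFilterConfig()
    if not slices:
        return []
    # the band is relative to the source volume depth; slices produced by
    # slice_axial carry it, making repeated application idempotent
    depth = slices[0].n_slices or (max(s.slice_index for s in slices) + 1)
    trim = depth * (1.0 - cfg.central_band_fraction) / 2.0
    lo = int(np.floor(trim))
    hi = depth - int(np.ceil(trim))
    return [
        s for s in slices
        if lo <= s.slice_index < hi
        and _lesion_pixels(s.mask, cfg.per_component) >= cfg.min_lesion_pixels
    ]


def skull_strip(sl: SlicePair, morphology_radius: int = 2
                ) -> tuple[SlicePair, np.ndarray]:
    """Remove skull/non-brain tissue from one slice.

    Contrast stretch to [0, 1] -> histogram equalization -> Otsu threshold ->
    morphological opening then closing -> keep largest connected component ->
    fill holes.  The output image is the input multiplied by the brain mask;
    the lesion mask is never modified.
    """
    img = sl.image
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("degenerate intensity histogram")
    stretched = (img - lo) / (hi - lo)
    equalized = exposure.equalize_hist(stretched)
    fg = equalized > filters.threshold_otsu(equalized)
    selem = morphology.disk(morphology_radius)
    fg = morphology.opening(fg, selem)
    fg = morphology.closing(fg, selem)
    labels, n = ndimage.label(fg)
    if n > 0:
        largest = 1 + int(np.argmax(np.bincount(labels.ravel())[1:]))
        fg = labels == largest
    brain_mask = ndimage.binary_fill_holes(fg)
    out = SlicePair(image=img * brain_mask, mask=sl.mask,
                    patient_id=sl.patient_id, slice_index=sl.slice_index,
                    tag=sl.tag, n_slices=sl.n_slices)
    return out, brain_mask.astype(np.uint8)


def denoise_nlmeans(image: np.ndarray, patch_size: int = 3, search_window: int = 11,
                    filter_strength: float = 10.0) -> np.ndarray:
    """Non-local means denoising.

    Each output pixel is the weighted average of pixels within the search
    window; the weight of candidate q for pixel p is
    exp(-||patch(p) - patch(q)||^2 / h^2), normalized per pixel.  Patches are
    read from a reflect-padded image so border pixels are well defined.
    """
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    if search_window < patch_size:
        raise ValueError("search_window must be >= patch_size")
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite pixels in input image")
    H, W = img.shape
    pp = patch_size // 2
    sw = search_window // 2
    pad = sw + pp
    P = np.pad(img, pad, mode="reflect")
    h2 = float(filter_strength) ** 2
    num = np.zeros((H, W))
    den = np.zeros((H, W))
    for di in range(-sw, sw + 1):
        for dj in range(-sw, sw + 1):
            shifted = P[pad + di - pp: pad + di + H + pp, pad + dj - pp: pad + dj + W + pp]
            base = P[pad - pp: pad + H + pp, pad - pp: pad + W + pp]
            d2 = (base - shifted) ** 2
            ssd = ndimage.uniform_filter(d2, patch_size)[pp:pp + H, pp:pp + W] \
                * patch_size ** 2
            w = np.exp(-ssd / h2)
            num += w * P[pad + di: pad + di + H, pad + dj: pad + dj + W]
            den += w
    return num / den


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust noise estimate from the median absolute Laplacian residual."""
    lap = ndimage.laplace(np.asarray(image, dtype=np.float64))
    return float(np.median(np.abs(lap)) / 0.6745 / np.sqrt(20.0))


def bias_correct(image: np.ndarray, method: str = "polynomial", degree: int = 2,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Correct smooth multiplicative intensity inhomogeneity.

    polynomial: least-squares fit of a degree-``degree`` surface to
    log-intensity over the brain region (``mask``, default: positive pixels),
    then division by exp(fit) renormalized to unit mean over that region.
    delegated_n4: SimpleITK's N4 implementation behind the same interface.
    none: identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("bias correction expects a nonnegative image")
    if method == "none":
        return img.copy()
    region = (img > 0) if mask is None else np.asarray(mask, dtype=bool)
    if region.sum() == 0:
        raise ValueError("empty brain region: nothing to fit the bias field on")
    if method == "polynomial":
        H, W = img.shape
        yy, xx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W), indexing="ij")
        terms = [xx ** a * yy ** b
                 for a in range(degree + 1) for b in range(degree + 1 - a)]
        A = np.stack([t[region] for t in terms], axis=1)
        logs = np.log(np.maximum(img[region], 1e-12))
        coef, *_ = np.linalg.lstsq(A, logs, rcond=None)
        fit = sum(c * t for c, t in zip(coef, terms))
        fld = np.exp(fit - fit[region].mean())
        fld /= fld[region].mean()
        return img / fld
    if method == "delegated_n4":
        return _n4_correct(img, region)
    raise ValueError(f"unknown bias correction method: {method!r}")


def _n4_correct(img: np.ndarray, region: np.ndarray) -> np.ndarray:
    import SimpleITK as sitk

    image = sitk.GetImageFromArray(img.astype(np.float32))
    mask = sitk.GetImageFromArray(region.astype(np.uint8))
    corrected = sitk.N4BiasFieldCorrection(image, mask)
    return np.asarray(sitk.GetArrayFromImage(corrected), dtype=np.float64)


def resize_pair(sl: SlicePair, target: tuple[int, int] = (256, 256)) -> SlicePair:
    """Bilinear image resize; nearest-neighbor mask resize, re-binarized."""
    if min(target) <= 0:
        raise ValueError("target size must be positive")
    if sl.image.shape == tuple(target):
        return sl
    img = transform.resize(sl.image, target, order=1, preserve_range=True,
                           anti_aliasing=False)
    msk = transform.resize(sl.mask.astype(np.float64), target, order=0,
                           preserve_range=True, anti_aliasing=False)
    return SlicePair(image=img, mask=(msk > 0.5).astype(np.uint8),
                     patient_id=sl.patient_id, slice_index=sl.slice_index,
                     tag=sl.tag, n_slices=sl.n_slices)


def preprocess_slice(sl: SlicePair, cfg: PreprocessConfig) -> SlicePair:
    """Apply skull stripping, denoising, bias correction, resizing, and
    normalization to one retained slice."""
    out = sl
    if cfg.skull_strip:
        out, _ = skull_strip(out, morphology_radius=cfg.morphology_radius)
    img = out.image
    if cfg.denoise == "nlmeans":
        h = cfg.nlmeans_filter_strength
        if h is None:
            h = max(0.8 * estimate_noise_sigma(img), 1e-3)
        img = denoise_nlmeans(img, cfg.nlmeans_patch_size, cfg.nlmeans_search_window, h)
    elif cfg.denoise != "none":
        raise ValueError(f"unknown denoise method: {cfg.denoise!r}")
    if cfg.bias_correction != "none":
        method = cfg.bias_correction
        img = bias_correct(np.maximum(img, 0.0), method=method, degree=cfg.bias_poly_degree)
    out = SlicePair(image=img, mask=out.mask, patient_id=out.patient_id,
                    slice_index=out.slice_index, tag=out.tag, n_slices=out.n_slices)
    out = resize_pair(out, cfg.target_size)
    if cfg.normalize == "minmax":
        lo, hi = out.image.min(), out.image.max()
        img = (out.image - lo) / (hi - lo) if hi > lo else np.zeros_like(out.image)
        out = SlicePair(image=img, mask=out.mask, patient_id=out.patient_id,
                        slice_index=out.slice_index, tag=out.tag,
                        n_slices=out.n_slices)
    return out


def preprocess_volume(vol: VolumePair, prep_cfg: PreprocessConfig | None = None,
                      filter_cfg: SliceFilterConfig | None = None) -> list[SlicePair]:
    """Slice, filter, and fully preprocess one volume."""
    prep_cfg = prep_cfg or PreprocessConfig()
    retained = select_slices(slice_axial(vol), filter_cfg)
    return [preprocess_slice(s, prep_cfg) for s in retained]


def write_slices(slices: list[SlicePair], out_dir, manifest_name: str = "manifest.csv"
                 ) -> pd.DataFrame:
    """Write 8-bit grayscale image PNGs and 0/255 mask PNGs plus a manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in slices:
        stem = f"{s.patient_id}_s{s.slice_index:04d}_{s.tag}"
        lo, hi = s.image.min(), s.image.max()
        img8 = np.zeros_like(s.image) if hi <= lo else (s.image - lo) / (hi - lo) * 255
        Image.fromarray(img8.astype(np.uint8)).save(out / f"{stem}_img.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out / f"{stem}_mask.png")
        rows.append({"patient_id": s.patient_id, "slice_index": s.slice_index,
                     "tag": s.tag, "retained": True, "lesion_pixels": int(s.mask.sum()),
                     "image": f"{stem}_img.png", "mask": f"{stem}_mask.png"})
    manifest = pd.DataFrame(rows, columns=["patient_id", "slice_index", "tag",
                                           "retained", "lesion_pixels", "image", "mask"])
    manifest.to_csv(out / manifest_name, index=False)
    return manifest
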