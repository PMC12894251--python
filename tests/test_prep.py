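"""Preprocessing pipeline: loading, slicing, slice retention, skull
stripping, NL-means, bias correction, resizing."""

import numpy as np
import pytest

from lesionseg.core import SlicePair, VolumePair
from lesionseg.phantom import PhantomSpec, generate_phantom, write_phantom
from lesionseg.prep import (PreprocessConfig, SliceFilterConfig, bias_correct,
                            denoise_nlmeans, load_volume_pair, preprocess_volume,
                            resize_pair, select_slices, skull_strip, slice_axial,
                            write_slices)


# ---------------------------------------------------------------- loading

def test_load_round_trips_phantom(tmp_path, clean_phantom):
    img_path, mask_path = write_phantom(clean_phantom, tmp_path / "p")
    vol = load_volume_pair(img_path, mask_path, "p")
    assert np.array_equal(vol.mask, clean_phantom.mask)


def test_load_binarizes_mask_at_positive(tmp_path):
    import nibabel as nib
    arr = np.zeros((20, 20, 20), dtype=np.float32)
    msk = np.zeros((20, 20, 20), dtype=np.float32)
    msk[3:5, 3:5, 3:5] = 255.0
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "i.nii.gz"))
    nib.save(nib.Nifti1Image(msk, np.eye(4)), str(tmp_path / "m.nii.gz"))
    vol = load_volume_pair(tmp_path / "i.nii.gz", tmp_path / "m.nii.gz", "p")
    assert set(np.unique(vol.mask)) == {0, 1}


def test_load_shape_mismatch_names_both_shapes(tmp_path):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.zeros((16, 16, 16), dtype=np.float32), np.eye(4)),
             str(tmp_path / "i.nii.gz"))
    nib.save(nib.Nifti1Image(np.zeros((8, 8, 8), dtype=np.float32), np.eye(4)),
             str(tmp_path / "m.nii.gz"))
    with pytest.raises(ValueError, match=r"16.*8"):
        load_volume_pair(tmp_path / "i.nii.gz", tmp_path / "m.nii.gz", "p")


# ---------------------------------------------------------------- slicing

def test_slice_axial_is_the_inverse_of_stacking(clean_phantom):
    vol = clean_phantom.as_volume_pair()
    slices = slice_axial(vol)
    assert len(slices) == vol.intensity.shape[0]
    assert [s.slice_index for s in slices] == list(range(len(slices)))
    np.testing.assert_array_equal(slices[5].image, vol.intensity[5])
    rebuilt = np.stack([s.image for s in slices])
    np.testing.assert_array_equal(rebuilt, vol.intensity)


def _slices_with_lesion_sizes(depth, sizes):
    """Depth-``depth`` stack with given lesion pixel counts per slice index."""
    out = []
    for k in range(depth):
        msk = np.zeros((32, 32), dtype=np.uint8)
        n = sizes.get(k, 0)
        msk.flat[:n] = 1
        out.append(SlicePair(image=np.ones((32, 32)), mask=msk,
                             patient_id="p", slice_index=k))
    return out


def test_select_slices_band_then_min_lesion_rule():
    """Depth 20, band 0.70 keeps indices 3..16; lesions of sizes 3/5/9 on
    slices 7/10/13 plus a 50-pixel lesion on out-of-band slice 1 leave
    exactly slices 10 and 13 (hand-enumerated from the stated rule)."""
    slices = _slices_with_lesion_sizes(20, {7: 3, 10: 5, 13: 9, 1: 50})
    kept = select_slices(slices, SliceFilterConfig(min_lesion_pixels=5,
                                                   central_band_fraction=0.70))
    assert [s.slice_index for s in kept] == [10, 13]


def test_select_slices_boundary_at_five_pixels():
    slices = _slices_with_lesion_sizes(20, {10: 4, 11: 5})
    kept = select_slices(slices, SliceFilterConfig())
    assert [s.slice_index for s in kept] == [11]


def test_select_slices_empty_mask_gives_empty_output():
    slices = _slices_with_lesion_sizes(10, {})
    assert select_slices(slices, SliceFilterConfig()) == []


def test_select_slices_idempotent(noisy_phantom):
    slices = slice_axial(noisy_phantom.as_volume_pair())
    cfg = SliceFilterConfig()
    once = select_slices(slices, cfg)
    twice = select_slices(once, cfg)
    assert [s.slice_index for s in once] == [s.slice_index for s in twice]


# ---------------------------------------------------------------- skull strip

def _ring_slice():
    """Disk 'brain' (level 100) plus a separated bright ring (level 180)."""
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    r = np.hypot(yy - 31.5, xx - 31.5)
    img = np.zeros((64, 64))
    img[r <= 20] = 100.0
    img[(r > 25) & (r <= 28)] = 180.0
    msk = np.zeros((64, 64), dtype=np.uint8)
    msk[30:33, 30:33] = 1
    return SlicePair(image=img, mask=msk, patient_id="p", slice_index=0), r


def test_skull_strip_removes_ring_keeps_brain():
    sl, r = _ring_slice()
    stripped, brain_mask = skull_strip(sl)
    ring = (r > 25) & (r <= 28)
    disk = r <= 19
    assert brain_mask[ring].sum() == 0          # ring excluded
    assert brain_mask[disk].mean() > 0.99       # brain kept
    assert np.array_equal(stripped.mask, sl.mask)   # lesion mask untouched
    assert np.array_equal(stripped.image, sl.image * brain_mask)


def test_skull_strip_brain_only_slice_keeps_bright_pixels():
    from skimage import filters
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    r = np.hypot(yy - 31.5, xx - 31.5)
    img = np.where(r <= 22, 100.0, 0.0) + np.abs(
        np.random.default_rng(0).normal(0, 1, (64, 64)))
    sl = SlicePair(image=img, mask=np.zeros((64, 64), np.uint8),
                   patient_id="p", slice_index=0)
    _, brain_mask = skull_strip(sl)
    above = img > filters.threshold_otsu(img)
    assert brain_mask[above].mean() > 0.99


def test_skull_strip_constant_image_raises():
    sl = SlicePair(image=np.full((32, 32), 3.0), mask=np.zeros((32, 32), np.uint8),
                   patient_id="p", slice_index=0)
    with pytest.raises(ValueError, match="degenerate intensity histogram"):
        skull_strip(sl)


# ---------------------------------------------------------------- NL-means

def brute_nlmeans(image, patch_size, search_window, h):
    """Double-loop oracle with the same reflect-padded patch definition."""
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    pp, sw = patch_size // 2, search_window // 2
    pad = sw + pp
    P = np.pad(img, pad, mode="reflect")
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            num = den = 0.0
            for di in range(-sw, sw + 1):
                for dj in range(-sw, sw + 1):
                    ssd = 0.0
                    for u in range(-pp, pp + 1):
                        for v in range(-pp, pp + 1):
                            d = (P[pad + i + u, pad + j + v]
                                 - P[pad + i + di + u, pad + j + dj + v])
                            ssd += d * d
                    w = np.exp(-ssd / h ** 2)
                    num += w * P[pad + i + di, pad + j + dj]
                    den += w
            out[i, j] = num / den
    return out


def test_nlmeans_constant_image_is_fixed_point():
    img = np.full((16, 16), 7.0)
    np.testing.assert_allclose(denoise_nlmeans(img, 3, 5, 1.0), img)


def test_nlmeans_matches_brute_force_oracle():
    img = np.random.default_rng(3).random((9, 9)) * 10
    fast = denoise_nlmeans(img, patch_size=3, search_window=5, filter_strength=2.0)
    slow = brute_nlmeans(img, 3, 5, 2.0)
    np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)


def test_nlmeans_reduces_variance_on_noisy_slice(noisy_phantom):
    sl = noisy_phantom.intensity[12]
    brain = sl > 50
    den = denoise_nlmeans(sl, 3, 7, filter_strength=10.0)
    assert den[brain].var() < sl[brain].var()


def test_nlmeans_rejects_nonfinite_and_bad_params():
    with pytest.raises(ValueError, match="non-finite"):
        denoise_nlmeans(np.array([[np.nan, 1.0], [0.0, 1.0]]), 1, 3, 1.0)
    with pytest.raises(ValueError, match="odd"):
        denoise_nlmeans(np.ones((4, 4)), 2, 5, 1.0)


# ---------------------------------------------------------------- bias

def test_bias_correct_identity_when_unbiased():
    """Lesion-free constant brain: degree-2 fit is constant, unit-mean
    renormalization makes the correction exact identity."""
    yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    r = np.hypot(yy - 31.5, xx - 31.5)
    img = np.where(r <= 22, 100.0, 0.0)
    out = bias_correct(img, method="polynomial", degree=2)
    brain = img > 0
    np.testing.assert_allclose(out[brain], img[brain], rtol=1e-6)


def test_bias_correct_reduces_cv_of_biased_tissue(noisy_phantom):
    """Known degree-2 multiplicative bias: coefficient of variation of the
    healthy brain tissue strictly decreases after correction."""
    k = 12
    sl = np.maximum(noisy_phantom.intensity[k], 0.0)
    lesions = noisy_phantom.mask[k].astype(bool)
    tissue = (sl > 50) & ~lesions
    out = bias_correct(sl, method="polynomial", degree=2, mask=tissue)
    cv_before = sl[tissue].std() / sl[tissue].mean()
    cv_after = out[tissue].std() / out[tissue].mean()
    assert cv_after < cv_before


def test_bias_correct_none_is_identity_and_errors():
    img = np.random.default_rng(0).random((8, 8))
    np.testing.assert_array_equal(bias_correct(img, method="none"), img)
    with pytest.raises(ValueError, match="brain region"):
        bias_correct(np.zeros((8, 8)), method="polynomial")
    with pytest.raises(ValueError):
        bias_correct(-img, method="polynomial")


# ---------------------------------------------------------------- resize

def test_resize_noop_and_binary_contract():
    sl = SlicePair(image=np.random.default_rng(1).random((64, 64)),
                   mask=(np.random.default_rng(2).random((64, 64)) > 0.8).astype(np.uint8),
                   patient_id="p", slice_index=0)
    same = resize_pair(sl, (64, 64))
    np.testing.assert_array_equal(same.image, sl.image)
    up = resize_pair(sl, (128, 128))
    assert up.image.shape == (128, 128)
    assert set(np.unique(up.mask)) <= {0, 1}


def test_resize_nearest_neighbor_area_oracle():
    msk = np.zeros((128, 128), dtype=np.uint8)
    msk[60:64, 60:64] = 1
    sl = SlicePair(image=msk.astype(float), mask=msk, patient_id="p", slice_index=0)
    up = resize_pair(sl, (256, 256))
    assert int(up.mask.sum()) == 64   # each pixel maps to exactly 2x2


# ---------------------------------------------------------------- pipeline

def test_full_pipeline_deterministic_and_mask_preserving(noisy_phantom):
    cfg = PreprocessConfig(target_size=(64, 64), denoise="nlmeans",
                           nlmeans_search_window=5, bias_correction="polynomial")
    a = preprocess_volume(noisy_phantom.as_volume_pair(), cfg, SliceFilterConfig())
    b = preprocess_volume(noisy_phantom.as_volume_pair(), cfg, SliceFilterConfig())
    assert len(a) > 0
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.image, sb.image)
        np.testing.assert_array_equal(sa.mask, sb.mask)
        assert sa.image.shape == (64, 64)
        # masks pass through untouched except for the resize mapping
        assert set(np.unique(sa.mask)) <= {0, 1}


def test_write_slices_manifest(tmp_path, clean_phantom):
    slices = select_slices(slice_axial(clean_phantom.as_volume_pair()),
                           SliceFilterConfig())
    manifest = write_slices(slices[:3], tmp_path)
    assert list(manifest.columns) == ["patient_id", "slice_index", "tag",
                                      "retained", "lesion_pixels", "image", "mask"]
    assert len(manifest) == 3
    assert (tmp_path / manifest.iloc[0]["image"]).exists()
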