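"""Synthetic FLAIR-like brain phantoms with exact lesion ground truth.

The phantom emulates the gross intensity structure of an axial FLAIR series:
a dark background, an ellipsoidal "brain" of brighter tissue, an optional
bright skull ring separated from the brain by a dark gap, small hyperintense
spherical lesions, a smooth multiplicative bias field, and additive Gaussian
noise.  Reference levels are fixed (background 0, brain tissue 100, skull
ring 180, lesion = 100 x contrast before bias/noise) so that downstream
oracle checks can be exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import VolumePair, as_binary

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "generate_phantom",
    "write_phantom",
    "generate_cohort",
    "BACKGROUND_LEVEL",
    "BRAIN_LEVEL",
    "SKULL_LEVEL",
]

BACKGROUND_LEVEL = 0.0
BRAIN_LEVEL = 100.0
SKULL_LEVEL = 180.0

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume; identical spec + seed gives
    bit-identical output."""

    shape: tuple[int, int, int] = (32, 128, 128)
    brain_axes: tuple[float, float, float] = (13.0, 52.0, 44.0)
    skull_ring: bool = True
    skull_thickness: float = 3.0
    lesion_count: int = 8
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)
    lesion_contrast: float = 1.6
    bias_amplitude: float = 0.2
    noise_sigma: float = 4.0
    seed: int = 0

    def validate(self):
        if any(s < 16 for s in self.shape):
            raise ValueError(f"shape dimensions must be >= 16, got {self.shape}")
        if self.lesion_radius_range[0] < 1:
            raise ValueError("minimum lesion radius must be >= 1 voxel")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (min, max) with min <= max")
        if self.lesion_contrast <= 1:
            raise ValueError("lesion_contrast must exceed 1 (hyperintense lesions)")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be nonnegative")
        if self.bias_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("bias_amplitude and noise_sigma must be nonnegative")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(_spec_to_dict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


@dataclass
class PhantomVolume:
    """3D intensity volume + aligned binary lesion mask."""

    intensity: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = "phantom"
    spec: PhantomSpec | None = field(default=None, repr=False)

    def as_volume_pair(self) -> VolumePair:
        return VolumePair(intensity=self.intensity, mask=self.mask,
                          patient_id=self.patient_id, voxel_spacing=self.voxel_spacing)


def _normalized_radius(shape, axes):
    """Per-voxel ellipsoidal coordinate rho (rho <= 1 inside the brain)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centers = [(s - 1) / 2.0 for s in shape]
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, axes))
    return np.sqrt(rho2)


def generate_phantom(spec: PhantomSpec, patient_id: str = "phantom") -> PhantomVolume:
    """Generate one phantom volume.

    Lesions are placed by rejection sampling (up to 1000 attempts each) as
    non-overlapping spheres fully inside the brain ellipsoid, pairwise
    separated by more than one voxel so that 26-connected component labeling
    recovers exactly ``lesion_count`` components.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho = _normalized_radius(spec.shape, spec.brain_axes)
    brain = rho <= 1.0

    intensity = np.full(spec.shape, BACKGROUND_LEVEL, dtype=np.float64)
    intensity[brain] = BRAIN_LEVEL
    if spec.skull_ring:
        # ring outside a dark gap around the brain, in ellipsoidal coordinates
        ring_inner = 1.15
        ring_outer = ring_inner + spec.skull_thickness / min(spec.brain_axes)
        ring = (rho > ring_inner) & (rho <= ring_outer)
        intensity[ring] = SKULL_LEVEL

    mask = np.zeros(spec.shape, dtype=np.uint8)
    centers = np.array([(s - 1) / 2.0 for s in spec.shape])
    placed: list[tuple[np.ndarray, float]] = []
    rmin, rmax = spec.lesion_radius_range
    for lesion_idx in range(spec.lesion_count):
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            radius = rng.uniform(rmin, rmax)
            center = np.array([rng.uniform(0, s - 1) for s in spec.shape])
            # fully inside the brain: ellipsoidal distance of the sphere's
            # farthest point, conservatively via the smallest semi-axis
            margin = np.sqrt(sum(((center[i] - centers[i]) / spec.brain_axes[i]) ** 2
                                 for i in range(3)))
            if margin + (radius + 1.0) / min(spec.brain_axes) > 1.0:
                continue
            if any(np.linalg.norm(center - c0) <= radius + r0 + 2.0 for c0, r0 in placed):
                continue
            placed.append((center, radius))
            break
        else:
            raise RuntimeError(
                f"could not place lesion {lesion_idx} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; reduce lesion_count or radius"
            )
        zz, yy, xx = np.ogrid[tuple(slice(0, s) for s in spec.shape)]
        sphere = ((zz - placed[-1][0][0]) ** 2 + (yy - placed[-1][0][1]) ** 2 +
                  (xx - placed[-1][0][2]) ** 2) <= placed[-1][1] ** 2
        mask[sphere] = 1

    intensity[mask == 1] = BRAIN_LEVEL * spec.lesion_contrast

    if spec.bias_amplitude > 0:
        grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in spec.shape], indexing="ij")
        coeffs = rng.normal(size=10)
        terms = [np.ones(spec.shape)] + list(grids) + \
            [g1 * g2 for i, g1 in enumerate(grids) for g2 in grids[i:]]
        poly = sum(c * t for c, t in zip(coeffs, terms))
        poly -= poly[brain].mean()
        peak = np.abs(poly[brain]).max()
        if peak > 0:
            poly /= peak
        intensity *= 1.0 + spec.bias_amplitude * poly

    if spec.noise_sigma > 0:
        intensity += rng.normal(0.0, spec.noise_sigma, spec.shape)

    return PhantomVolume(intensity=intensity, mask=mask, patient_id=patient_id, spec=spec)


def write_phantom(vol: PhantomVolume, path) -> tuple[Path, Path]:
    """Write intensity and mask as NIfTI files ``<path>_flair.nii.gz`` and
    ``<path>_mask.nii.gz`` sharing one affine."""
    as_binary(vol.mask)  # reject non-binary masks before touching disk
    prefix = Path(path)
    if not prefix.parent.exists():
        raise IOError(f"parent directory does not exist: {prefix.parent}")
    # volumes are (axial z, y, x); NIfTI stores (x, y, z)
    affine = np.diag([vol.voxel_spacing[2], vol.voxel_spacing[1],
                      vol.voxel_spacing[0], 1.0])
    img_path = prefix.with_name(prefix.name + "_flair.nii.gz")
    mask_path = prefix.with_name(prefix.name + "_mask.nii.gz")
    nib.save(nib.Nifti1Image(vol.intensity.transpose(2, 1, 0).astype(np.float32),
                             affine), str(img_path))
    nib.save(nib.Nifti1Image(vol.mask.transpose(2, 1, 0).astype(np.uint8),
                             affine), str(mask_path))
    return img_path, mask_path


def generate_cohort(n_patients: int, spec: PhantomSpec, seed: int | None = None
                    ) -> list[PhantomVolume]:
    """Generate an independent phantom per patient (seeds spawned from one
    root seed so the whole cohort is reproducible)."""
    root = spec.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(root).generate_state(n_patients) % (2 ** 31)
    cohort = []
    for i, s in enumerate(child_seeds):
        pspec = dataclasses.replace(spec, seed=int(s))
        cohort.append(generate_phantom(pspec, patient_id=f"patient{i:03d}"))
    return cohort
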