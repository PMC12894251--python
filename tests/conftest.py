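import numpy as np
import pytest

from lesionseg.core import SlicePair
from lesionseg.model import (AsppConfig, DecoderConfig, DhaConfig,
                             EncoderConfig, ModelConfig)
from lesionseg.phantom import PhantomSpec, generate_phantom


def tiny_model_config(seed: int = 0) -> ModelConfig:
    """Smallest config that preserves the 13-conv/5-block topology; used by
    fast training-plumbing tests at 32x32."""
    return ModelConfig(
        encoder=EncoderConfig(block_widths=(4, 4, 8, 8, 8)),
        aspp=AsppConfig(branch_channels=8, out_channels=8),
        decoder=DecoderConfig(level_widths=(4, 4, 8, 8, 8)),
        dha=DhaConfig(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and bias-free phantom: intensities at exact reference levels."""
    spec = PhantomSpec(shape=(24, 64, 64), brain_axes=(10.0, 26.0, 22.0),
                       lesion_count=4, lesion_radius_range=(2.0, 3.0),
                       noise_sigma=0.0, bias_amplitude=0.0, seed=5)
    return generate_phantom(spec, patient_id="clean")


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(shape=(24, 64, 64), brain_axes=(10.0, 26.0, 22.0),
                       lesion_count=4, lesion_radius_range=(2.0, 3.0),
                       noise_sigma=4.0, bias_amplitude=0.2, seed=6)
    return generate_phantom(spec, patient_id="noisy")


def square_slice(size=32, square=(10, 14, 10, 14), patient="p0", index=0):
    """A slice with a filled rectangular lesion, for geometric oracles."""
    img = np.zeros((size, size))
    msk = np.zeros((size, size), dtype=np.uint8)
    r0, r1, c0, c1 = square
    msk[r0:r1, c0:c1] = 1
    img[r0:r1, c0:c1] = 1.0
    return SlicePair(image=img, mask=msk, patient_id=patient, slice_index=index)
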