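import numpy as np
import pytest

from vcore.encoder import EncoderConfig, EncoderParams
from vcore.phantom import PhantomSpec, generate_phantom_stack


@pytest.fixture(scope="session")
def small_stack():
    """A 4-section 256x256 phantom with modest rigid motion, no warp."""
    spec = PhantomSpec(
        image_size=(256, 256), n_sections=4, max_rotation=8.0,
        max_translation=10.0, max_scale_dev=0.04, warp_amplitude=0.0, seed=3,
    )
    return generate_phantom_stack(spec)


@pytest.fixture(scope="session")
def tiny_encoder():
    """A small divided-attention encoder for fast forward passes."""
    cfg = EncoderConfig(image_size=16, patch_size=8, depth=3, embed_dim=16,
                        n_heads=2, n_blocks=2)
    return cfg, EncoderParams.init(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
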