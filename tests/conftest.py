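import numpy as np
import pytest

from ndaikit import ForwardModel, PixelMask, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20230403)


@pytest.fixture
def full_mask():
    def make(shape):
        return PixelMask(np.ones(shape, dtype=bool))

    return make


@pytest.fixture
def noiseless_model():
    return ForwardModel(noise_sd=0.0)


@pytest.fixture
def two_disc_spec():
    """Two discs with known pigments: disc 2 has far more anthocyanin."""
    return SceneSpec(
        layout="discs",
        n_objects=2,
        width=96,
        height=96,
        anthocyanin=[300.0, 1400.0],
        chlorophyll=[1.0, 1.0],
        seed=7,
    )
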