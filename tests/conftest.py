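import numpy as np
import pytest

from nmphkit.features import make_toy_extractor
from nmphkit.synthesis import SynthesisSpec


@pytest.fixture(scope="session")
def extractor():
    """Default 3-layer toy extractor (two constrained taps, one target)."""
    return make_toy_extractor(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def quick_spec():
    """Small, fast synthesis settings for unit tests."""
    return SynthesisSpec(
        init_iters=30,
        tune_iters=40,
        volleys=1,
        window_fraction=1.0,
        crop_quantile=0.0,
        image_size=24,
        seed=123,
    )
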