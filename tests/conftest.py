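import numpy as np
import pytest

from pcgkit import BeatTemplate


@pytest.fixture
def clean_template() -> BeatTemplate:
    """Default beat morphology: no murmur, no noise, no jitter."""
    return BeatTemplate()


@pytest.fixture
def noisy_template() -> BeatTemplate:
    """Study-condition morphology for an abnormal beat."""
    return BeatTemplate(murmur_amplitude=0.5, noise_sd=0.05, jitter_fraction=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
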