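import numpy as np
import pytest

from mfnet.data_io import OCTSample, UNLABELED
from mfnet.synthetic_data import SynthParams, synth_samples


@pytest.fixture(scope="session")
def tiny_params():
    """Small-image generator settings used by fast training smokes."""
    return SynthParams(image_size=(64, 64), seed=7000)


@pytest.fixture(scope="session")
def tiny_samples(tiny_params):
    return synth_samples(16, tiny_params)


@pytest.fixture(scope="session")
def tiny_unlabeled(tiny_params):
    from dataclasses import replace
    raw = synth_samples(6, replace(tiny_params, seed=8000))
    return [OCTSample(image=s.image, mask=None, id=f"u{i}",
                      provenance=UNLABELED) for i, s in enumerate(raw)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
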