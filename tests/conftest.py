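import numpy as np
import pytest

from mdam_drnet.fixtures import DEFAULT_CLASS_SPECS, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def class_specs():
    return {s.class_name: s for s in DEFAULT_CLASS_SPECS}


@pytest.fixture(scope="session")
def small_dataset():
    """Seven-class synthetic set, 10 images per class at 48x48."""
    return make_dataset(per_class=10, size=(48, 48), seed=7)
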