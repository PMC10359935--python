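import numpy as np
import pytest

from irispaint.synthetic import IrisSpec, generate_iris


@pytest.fixture(scope="session")
def small_iris():
    """A 128×128 synthetic iris (image, gt) pair used across modules."""
    spec = IrisSpec(image_size=128, pupil_radius=20, iris_radius=50,
                    texture_seed=7)
    return generate_iris(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
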