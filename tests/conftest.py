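import numpy as np
import pytest

from priorseg.phantom import PhantomSpec, make_template, sample_subject


@pytest.fixture(scope="session")
def template64():
    """Default 64-cube template phantom (image, labels)."""
    return make_template(PhantomSpec())


@pytest.fixture(scope="session")
def template32():
    return make_template(PhantomSpec(grid_shape=(32, 32, 32)))


@pytest.fixture(scope="session")
def subject64(template64):
    """One deformed subject with lesions at default conditions."""
    return sample_subject(template64, PhantomSpec(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
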