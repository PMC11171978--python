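import numpy as np
import pytest

from tendonquant.synthetic import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """A fixed phantom with lesions and a fragmented bone band."""
    return generate_phantom(PhantomSpec(seed=7, lesion_count=2, bone_n_gaps=2))
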