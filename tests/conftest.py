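import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20251115 % 2**31)


@pytest.fixture
def surd_1000(rng):
    from sqrkit import generate_surd

    return generate_surd(1000, rng)
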