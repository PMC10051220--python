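import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_image(rng):
    return rng.standard_normal((8, 8))


@pytest.fixture
def complex_field(rng):
    from diffray.diffops import ComplexField
    z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    return ComplexField.from_complex(z)
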