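import numpy as np
import pytest

from fbrseg.orientation import build_kernel_bank


@pytest.fixture(scope="session")
def bank():
    """The default 360-kernel compass bank (33 px, radius 15)."""
    return build_kernel_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
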