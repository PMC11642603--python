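import numpy as np
import pytest

from dyaddraw.design import DesignParams, generate_design


@pytest.fixture(scope="session")
def paper_design():
    """Full-size design with the published defaults."""
    return generate_design(DesignParams(seed=7))


@pytest.fixture(scope="session")
def small_design():
    """Minimal balanced design (1 block of 48 per context)."""
    return generate_design(DesignParams(n_blocks_per_context=1, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
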