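import numpy as np
import pytest

from pedci import PhantomSpec, PipelineConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_phantom():
    """The default three-compartment phantom at seed 0 (shared, read-only)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick phantom for tests that only need structure."""
    return generate_phantom(
        PhantomSpec(shape=(120, 160), dome_width_px=120, dome_height_px=50, seed=1)
    )
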