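import numpy as np
import pytest

from trenchroot import FrameSpec, TEST_FRAME
from trenchroot.synth import SynthConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def full_frame():
    """Full-scale frame: 1536 x 1536 px, 25.6 px/cm."""
    return FrameSpec()


@pytest.fixture(scope="session")
def test_frame():
    """Desk-scale frame: 384 x 384 px, 6.4 px/cm, same 60 x 60 cm wall."""
    return TEST_FRAME


@pytest.fixture(scope="session")
def toy_frame():
    """Tiny frame for geometry tests: 64 x 64 px at 1 px/cm."""
    return FrameSpec(resolution_px_per_cm=1.0, width_cm=64, depth_cm=64)


@pytest.fixture(scope="session")
def desk_sample(test_frame):
    """One deterministic synthetic sample at desk scale."""
    return generate_sample(SynthConfig(n_roots=12, seed=7), test_frame)
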