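import numpy as np
import pytest
from hypothesis import settings

from potencybench import synthetic_data as sd

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_class():
    """One synthetic activity class under the default configuration."""
    return sd.generate_activity_class(sd.SyntheticSARConfig(), "CLS-A")


@pytest.fixture(scope="session")
def ladder_class():
    """A class large enough in every sub-range for the balanced ladder."""
    cfg = sd.SyntheticSARConfig(min_per_subrange=140, seed=7)
    return sd.generate_activity_class(cfg, "CLS-L")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fp_factory(rng):
    """Factory for random non-empty binary fingerprints (oracle tests)."""

    def make(n, n_bits=128, density=0.2):
        fps = (rng.random((n, n_bits)) < density).astype(np.uint8)
        for row in fps:  # ensure at least one set bit
            if row.sum() == 0:
                row[int(rng.integers(n_bits))] = 1
        return fps

    return make
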