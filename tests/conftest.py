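import numpy as np
import pytest

from cardiocohere import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast two-condition study: 4 subjects, short runs, no volumes."""
    return SimConfig(
        n_subjects=4,
        duration_s={"suspense": 150.0, "control": 120.0},
        missing_frac=0.05,
        seed=7,
    )


@pytest.fixture
def default_cfg():
    return SimConfig(seed=11)
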