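import numpy as np
import pytest

from delnet.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast, small but fully featured simulation configuration."""
    # 160 volumes at TR 2 s leave >= 240 s after dropping 15 and censoring
    return SimulationConfig(n_subjects=8, n_regions=20, n_volumes=160,
                            n_modules=4, seed=11)
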