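import numpy as np
import pytest

from entrack.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Desk-scale synthetic configuration used across module tests."""
    return SyntheticConfig(
        n_stimuli=4, n_participants=3, n_repetitions=2, n_channels=8,
        frontocentral_subset=(0, 1, 2), layer_sizes=(8, 8, 8, 8, 8),
        n_untrained=2, stim_duration_s=(5.5, 6.0), master_seed=7)
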