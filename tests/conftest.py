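import numpy as np
import pytest

from popsignal import SessionConfig, SpikeTrainSet, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_set(rng):
    """Unstructured random spike trains, labels balanced."""
    n, j, k = 5, 24, 80
    spikes = (rng.random((n, j, k)) < 0.03).astype(np.uint8)
    labels = np.array([-1, 1] * (j // 2))
    return SpikeTrainSet(spikes=spikes, labels=labels)


@pytest.fixture(scope="session")
def small_session():
    """Small planted-effect session (fast, strongly separable)."""
    cfg = SessionConfig(
        n_neurons=12, n_trials_per_condition=40, n_bins=200,
        effect_window=(100.0, 200.0), modulation_depth=12.0, seed=7,
    )
    return generate_session(cfg)
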