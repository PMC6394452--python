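import numpy as np
import pytest

from eegdecode import DecodingConfig, EpochedDataset, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small two-condition design: 8 channels, signal on channels 1-4."""
    return SyntheticSpec(
        n_timepoints=20,
        n_channels=8,
        n_epochs=30,
        signal_value=1.0,
        signal_channels=(1, 2, 3, 4),
        signal_timepoints=(11, 20),
        rng_seed=7,
    )


@pytest.fixture
def tiny_config():
    return DecodingConfig(
        mode="spatial",
        window_width_ms=5,
        step_ms=5,
        k_folds=3,
        m_repetitions=2,
        rng_seed=11,
    )


def make_dataset(n_runs=1, n_conds=2, T=12, C=4, n_trials=6, seed=0,
                 with_labels=False):
    """Small deterministic dataset used across unit tests."""
    rng = np.random.default_rng(seed)
    data = {
        (r, c): rng.normal(size=(T, C, n_trials))
        for r in range(1, n_runs + 1)
        for c in range(1, n_conds + 1)
    }
    labels = None
    if with_labels:
        labels = {k: rng.uniform(-1, 1, size=n_trials) for k in data}
    return EpochedDataset(data=data, svr_labels=labels)


@pytest.fixture
def small_dataset():
    return make_dataset()
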