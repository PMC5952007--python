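import numpy as np
import pytest

from pacbci.core import CANONICAL_BANDS, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bands():
    return CANONICAL_BANDS


def make_epochs(n_trials=6, n_channels=3, n_samples=64, fs=256.0,
                seed=0, n_classes=2, n_sessions=2):
    rng = np.random.default_rng(seed)
    return EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        fs=fs,
        channels=[f"ch{i}" for i in range(n_channels)],
        class_label=1 + np.arange(n_trials) % n_classes,
        session_id=1 + np.arange(n_trials) % n_sessions,
        attend=(np.arange(n_trials) % 2).astype(bool),
        t0=0.0,
    )


@pytest.fixture
def small_epochs():
    return make_epochs()
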