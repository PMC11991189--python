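import numpy as np
import pytest

from eegrecon import EpochSet, SynthConfig, generate, standard_montage_22


@pytest.fixture(scope="session")
def montage():
    return standard_montage_22()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_epochs(n_trials=4, n_channels=3, n_samples=100, fs=250.0, seed=0,
                labels=None):
    """Small random EpochSet helper used across test modules."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_channels))
    classes = np.tile([1, 2], (n_trials + 1) // 2)[:n_trials]
    return EpochSet(data=rng.standard_normal((n_trials, n_channels,
                                              n_samples)),
                    fs=fs, labels=labels, classes=classes,
                    class_names={1: "left_hand", 2: "right_hand"})


@pytest.fixture(scope="session")
def small_synthetic():
    """20 trials/class at default noise, used by several modules."""
    return generate(SynthConfig(n_trials_per_class=20, seed=5))


@pytest.fixture(scope="session")
def det_map_epochs():
    """Noise-free set where all channels are exact linear functions of
    the 8 input channels."""
    return generate(SynthConfig(n_trials_per_class=6, deterministic_map=True,
                                snr_db=None, seed=7))
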