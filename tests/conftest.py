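import numpy as np
import pytest

from eegbench.core import EpochSet, NONTARGET, TARGET


def make_epochs(tensor, rate=500.0, labels=None, t_min=-0.3, onsets=None,
                channel_labels=None):
    """Build an EpochSet from a trials x channels x samples array."""
    tensor = np.asarray(tensor, dtype=float)
    n_trials, n_ch, n_samp = tensor.shape
    if labels is None:
        labels = [TARGET] * n_trials
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    times = t_min + np.arange(n_samp) / rate
    return EpochSet(
        tensor=tensor,
        epoch_times=times,
        labels=list(labels),
        keep_mask=np.ones(n_trials, dtype=bool),
        rate=rate,
        channel_labels=channel_labels,
        onsets=onsets,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160510)


@pytest.fixture
def small_epochs(rng):
    """20 trials x 2 channels x 550 samples of white noise, mixed labels."""
    tensor = rng.normal(0, 10, size=(20, 2, 550))
    labels = [TARGET if i % 4 == 0 else NONTARGET for i in range(20)]
    return make_epochs(tensor, labels=labels)
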