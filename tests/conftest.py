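import numpy as np
import pytest

from retrocue.containers import EpochSet
from retrocue.synth import SynthConfig, generate_epochs


def make_epochs(data, srate=250.0, t0=-2000.0, channel_names=None, table=None):
    """Small EpochSet around a raw array (trials x channels x time)."""
    data = np.asarray(data, dtype=float)
    step = 1000.0 / srate
    times = t0 + step * np.arange(data.shape[2])
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(
        data=data,
        srate=srate,
        times=times,
        channel_names=channel_names,
        trial_table=table,
    )


@pytest.fixture(scope="session")
def small_epochs():
    """One reduced-scale synthetic participant shared across read-only tests."""
    cfg = SynthConfig(n_trials_per_condition=48, srate=250.0, rng_seed=11)
    epochs, truth = generate_epochs(cfg)
    return cfg, epochs, truth
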