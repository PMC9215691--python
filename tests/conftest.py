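"""Shared fixtures: small synthetic segments and networks."""

import numpy as np
import pytest

from ictonet import (
    CHANNELS_1020,
    CouplingSpec,
    EEGSegment,
    FunctionalNetwork,
    cohort_baseline_spec,
    generate_segment,
    preprocess_segment,
)


@pytest.fixture(scope="session")
def strong_pair_spec():
    """20-channel spec with a single strongly coupled O1-O2 pair at lag pi/4."""
    n = 20
    k = np.zeros((n, n))
    lag = np.zeros((n, n))
    i, j = CHANNELS_1020.index("O1"), CHANNELS_1020.index("O2")
    k[i, j] = k[j, i] = 0.9
    lag[i, j] = np.pi / 4
    lag[j, i] = -np.pi / 4
    return CouplingSpec(pair_coupling=k, pair_lag=lag, seed=3)


@pytest.fixture(scope="session")
def strong_pair_segment(strong_pair_spec):
    return preprocess_segment(generate_segment(strong_pair_spec))


@pytest.fixture(scope="session")
def baseline_network():
    """A typical resting-EEG-like functional network (20 nodes), inferred
    from one baseline synthetic segment at reduced size."""
    from ictonet import build_network

    spec = cohort_baseline_spec(seed=11, fs=125.0, duration=10.0)
    seg = generate_segment(spec)
    pseg = preprocess_segment(seg, target_fs=125.0)
    return build_network(pseg, n_surrogates=19, seed=2)


@pytest.fixture
def tone_segment():
    """Two-channel 7 Hz tone segment at 250 Hz (cos and sin quadrature)."""
    fs = 250.0
    t = np.arange(int(fs * 8)) / fs
    data = np.vstack([np.cos(2 * np.pi * 7 * t), np.sin(2 * np.pi * 7 * t)])
    return EEGSegment(data=data, fs=fs, channel_labels=("A", "B"))
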