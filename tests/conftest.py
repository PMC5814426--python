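"""Shared fixtures: small synthetic recordings and tiny networks."""

import numpy as np
import pytest

import eegsex as e


@pytest.fixture(scope="session")
def montage():
    return e.default_montage()


@pytest.fixture(scope="session")
def short_recording():
    """10-s default-effect female recording at 500 Hz."""
    return e.generate_recording(e.EffectSpec(), sex=0, seed=11,
                                duration_s=10.0)


@pytest.fixture(scope="session")
def male_recording_120s():
    """Full-length (2-min) male recording for pipeline-shaped tests."""
    return e.generate_recording(e.EffectSpec(), sex=1, seed=21,
                                duration_s=120.0)


def tone_recording(freq_hz, fs=500.0, duration_s=10.0, amplitude=1.0,
                   n_channels=26):
    """Pure sinusoid on every channel (test signal, not EEG-like)."""
    m = e.default_montage()
    if n_channels < m.n_channels:
        m = m.subset(m.channel_names[:n_channels])
    t = np.arange(int(duration_s * fs)) / fs
    sig = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return e.Recording(subject_id="TONE", sex=0, fs=fs,
                       signal=np.tile(sig, (n_channels, 1)), montage=m)


@pytest.fixture(scope="session")
def tiny_net():
    """Small throw-away network for shape/gradient tests."""
    spec = e.ArchSpec(input_shape=(8, 32), layers=(
        e.ConvSpec(4, 3, 3), e.PoolSpec(2, 2), e.ConvSpec(6, 2, 3),
        e.DenseSpec(2)))
    return e.build_network(spec, seed=1)
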