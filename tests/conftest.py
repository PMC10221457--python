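import numpy as np
import pytest

from emgknee import GaitSimConfig, build_dataset, generate_dataset


@pytest.fixture(scope="session")
def clean_bout():
    """Noiseless 60-cycle simulated bout (angle and marker noise off)."""
    cfg = GaitSimConfig(n_cycles=60, noise_sd_deg=0.0, marker_noise_mm=0.0, seed=3)
    emg, markers, truth = generate_dataset(cfg)
    return cfg, emg, markers, truth


@pytest.fixture(scope="session")
def default_bout():
    """60-cycle bout at the default study conditions (SNR 20 dB, 1 deg noise)."""
    cfg = GaitSimConfig(n_cycles=60, seed=7)
    emg, markers, truth = generate_dataset(cfg)
    return cfg, emg, markers, truth


@pytest.fixture(scope="session")
def default_dataset(default_bout):
    _, emg, markers, _ = default_bout
    return build_dataset(emg, markers)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
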