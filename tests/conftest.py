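"""Shared fixtures: small synthetic datasets and preprocessed spectra."""

import pytest

from canopychl import (
    SmoothingConfig,
    SyntheticConfig,
    crop_interval,
    drop_boundary_bands,
    generate_dataset,
    savgol_smooth,
    split_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (196 samples, sensor noise on)."""
    return generate_dataset(SyntheticConfig(seed=1234))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free synthetic dataset for deterministic signal checks."""
    cfg = SyntheticConfig(noise_sd_additive=0.0, noise_sd_multiplicative=0.0, seed=77)
    return generate_dataset(cfg)


def preprocess(ds):
    s = drop_boundary_bands(ds.spectra, 1)
    s = crop_interval(s, 400.0, 800.0)
    return savgol_smooth(s, SmoothingConfig())


@pytest.fixture(scope="session")
def preprocessed_split(default_dataset):
    """Smoothed 400-800 nm spectra split into modeling / validation sets."""
    s = preprocess(default_dataset)
    return split_dataset(s, 0.84, seed=11)


@pytest.fixture(scope="session")
def noiseless_preprocessed(noiseless_dataset):
    return preprocess(noiseless_dataset)
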