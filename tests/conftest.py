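"""Shared fixtures: small phantom cohorts and an untrained desk model."""

import numpy as np
import pytest

from dualrad import ModelConfig, PhantomConfig, build_model, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16 benign + 16 malignant + 8 normal phantoms at 64x64."""
    cfg = PhantomConfig(image_size=64, n_benign=16, n_malignant=16, n_normal=8,
                        seed=42)
    samples, manifest = generate_cohort(cfg)
    return cfg, samples, manifest


@pytest.fixture(scope="session")
def desk_model():
    """An untrained desk-preset autoencoder (weights at initialization)."""
    return build_model(ModelConfig.desk(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
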