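"""Shared fixtures.

The trained tiny model is expensive (a few minutes of CPU) and is shared
session-wide by every test that needs a realistic trained network.
"""

from __future__ import annotations

import numpy as np
import pytest

from nervedetect.experiments import (
    build_training_pool,
    run_synthetic_benchmark,
    train_tiny_model,
)


@pytest.fixture(scope="session")
def tiny_pool():
    """100 positive + 100 negative training samples from synthetic slides."""
    return build_training_pool(n_pos=100, n_neg=100, start_seed=100)


@pytest.fixture(scope="session")
def tiny_trained(tiny_pool):
    """(model, history) of the tiny gated U-Net trained with seed 0."""
    return train_tiny_model(tiny_pool, seed=0)


@pytest.fixture(scope="session")
def synthetic_benchmark(tiny_trained):
    """CNN-vs-colour-filter benchmark on 5 held-out synthetic slides."""
    model, _ = tiny_trained
    return run_synthetic_benchmark(model, n_slides=5, start_seed=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
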