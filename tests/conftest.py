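"""Shared fixtures: a small model configuration and synthetic datasets."""

import numpy as np
import pytest
from hypothesis import settings

from mgfdta.data import generate_fixture, split
from mgfdta.model import ModelConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def small_config(**overrides) -> ModelConfig:
    base = dict(dc=32, dt=32, drug_embed_dim=32, protein_embed_dim=32,
                morgan_bits=512, avalon_bits=256, pca_dim=64, kmer_chunks=8,
                kmer_vocab_size=512, head_dims=(64, 32), batch_size=32,
                encoder_heads=2, epochs=2, seed=0)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture(scope="session")
def fixture_dataset():
    """200-pair synthetic dataset with planted signal, split 8:1:1."""
    return split(generate_fixture(seed=1), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g
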