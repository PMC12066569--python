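import numpy as np
import pytest

from amfgnn import SyntheticSpec, generate
from amfgnn.config import TrainConfig


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small planted-structure dataset for fast pipeline tests."""
    return generate(SyntheticSpec(n_drugs=20, n_diseases=15, latent_dim=4,
                                  assoc_density=0.15, noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale training configuration used by pipeline tests."""
    return TrainConfig(embed_dim=8, heads=2, epochs=3, knn_k=4, seed=7,
                       n_folds=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
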