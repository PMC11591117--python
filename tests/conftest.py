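import numpy as np
import pytest
from hypothesis import settings

from ccawoa import FeatureMatrix, generate_dual_view

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dual_view():
    """Modest planted dual-view problem shared across tests."""
    return generate_dual_view(
        n_per_class=50,
        n_classes=4,
        p1=20,
        p2=20,
        n_informative=6,
        latent_dim=6,
        noise_sd=0.6,
        view_correlation=0.9,
        seed=7,
    )


@pytest.fixture
def labeled_matrix(rng):
    values = rng.standard_normal((60, 8))
    labels = np.repeat([0, 1, 2], 20)
    return FeatureMatrix(values, labels)
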