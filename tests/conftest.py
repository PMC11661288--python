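import numpy as np
import pytest

from pvae.models import VAE
from pvae.synthetic_data import make_patch_dataset


@pytest.fixture(scope="session")
def patch_ds():
    """Small whitened synthetic patch dataset (8x8 patches, 64 dims)."""
    return make_patch_dataset(n_images=12, size=64, patch_size=8, seed=7)


@pytest.fixture(scope="session")
def patch_ds_16():
    """16x16-patch dataset matching the standard 256-pixel configuration."""
    return make_patch_dataset(n_images=8, size=64, patch_size=16, seed=7)


@pytest.fixture(scope="session")
def tiny_pvae(patch_ds):
    """A briefly trained Poisson VAE on the small patches."""
    return VAE(latent_dim=32, latent_family="poisson", n_steps=400,
               batch_size=32, random_state=0).fit(patch_ds.train)


@pytest.fixture(scope="session")
def planted_dictionary_problem():
    """Sparse data from a known 8-atom dictionary (recovery ground truth)."""
    rng = np.random.default_rng(3)
    M, K, n = 16, 8, 2000
    Phi_true = rng.standard_normal((M, K))
    Phi_true /= np.linalg.norm(Phi_true, axis=0)
    Z = np.zeros((n, K))
    for i in range(n):
        idx = rng.choice(K, size=rng.integers(1, 4), replace=False)
        Z[i, idx] = rng.exponential(2.0, size=idx.size) * \
            rng.choice([-1.0, 1.0], size=idx.size)
    X = Z @ Phi_true.T + 0.02 * rng.standard_normal((n, M))
    return X, Phi_true, Z
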