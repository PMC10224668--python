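import numpy as np
import pytest

import mtsgan as M


@pytest.fixture(scope="session")
def small_batch():
    """Default-structure simulated cohort, desk-scale N."""
    return M.simulate_batch(M.SimulatorConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def tiny_vae_config():
    return M.VAEConfig(hidden=16, latent_dim=3, batch_size=32)


@pytest.fixture(scope="session")
def pretrained(small_batch):
    """A reasonably converged dual-VAE shared across tests (expensive)."""
    cfg = M.VAEConfig(hidden=32, latent_dim=4, batch_size=32)
    vae, curves = M.pretrain(small_batch, M.LossWeights(), cfg,
                             epochs=40, seed=0)
    return vae, curves


def rand_batch(rng, n=6, T=8, j=3, k=2, labels=False):
    """Small random but valid mixed batch for structural tests."""
    x_cont = rng.normal(size=(n, T, j))
    x_disc = (rng.uniform(size=(n, T, k)) < 0.5).astype(float)
    lab = None
    if labels:
        cls = rng.integers(2, size=n)
        lab = np.eye(2)[cls]
    return M.MixedSeriesBatch(
        x_cont=x_cont, x_disc=x_disc, labels=lab,
        feature_names_cont=[f"v{i}" for i in range(j)],
        feature_names_disc=[f"d:i{i}" for i in range(k)])
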