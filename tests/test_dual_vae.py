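"""Loss-term oracles and pretraining behavior of the dual VAE."""

import numpy as np
import pytest
from scipy import integrate

import mtsgan as M
from mtsgan.autodiff import Tensor
from mtsgan.dual_vae import (VAEParams, kl_standard_normal, pooled,
                             reparameterize, semantic_loss)
from mtsgan import nn

from conftest import rand_batch


@pytest.fixture
def rng():
    return np.random.default_rng(11)


@pytest.fixture
def tiny_params(rng, tiny_vae_config):
    return VAEParams(rng, dim_cont=3, dim_disc=2, config=tiny_vae_config)


class TestEncodeDecode:
    def test_encode_means_deterministic(self, rng, tiny_params):
        batch = rand_batch(rng)
        a = M.encode(batch, tiny_params, sample=False)
        b = M.encode(batch, tiny_params, sample=False)
        np.testing.assert_array_equal(a.z_cont, b.z_cont)

    def test_encode_sampling_seeded(self, rng, tiny_params):
        batch = rand_batch(rng)
        a = M.encode(batch, tiny_params, sample=True, seed=3)
        b = M.encode(batch, tiny_params, sample=True, seed=3)
        c = M.encode(batch, tiny_params, sample=True, seed=4)
        np.testing.assert_array_equal(a.z_cont, b.z_cont)
        assert not np.array_equal(a.z_cont, c.z_cont)

    def test_degenerate_reparameterization_returns_mean(self, rng):
        mu = Tensor(rng.normal(size=(2, 3, 4)))
        logvar = Tensor(np.full((2, 3, 4), -1e8))
        z = reparameterize(mu, logvar, np.random.default_rng(0))
        np.testing.assert_allclose(z.data, mu.data, atol=1e-30)

    def test_decode_discrete_probabilities_in_unit_interval(self, rng, tiny_params):
        lat = M.LatentSeriesBatch(z_cont=rng.normal(size=(4, 5, 3)) * 5,
                                  z_disc=rng.normal(size=(4, 5, 3)) * 5)
        xc, pd_ = M.decode(lat, tiny_params)
        assert xc.shape == (4, 5, 3)
        assert pd_.shape == (4, 5, 2)
        assert np.all((pd_ > 0) & (pd_ < 1))
        xc2, pd2 = M.decode(lat, tiny_params)
        np.testing.assert_array_equal(xc, xc2)
        np.testing.assert_array_equal(pd_, pd2)


class TestELBO:
    def test_kl_zero_iff_posterior_is_prior(self):
        mu = Tensor(np.zeros((2, 3, 4)))
        lv = Tensor(np.zeros((2, 3, 4)))
        assert kl_standard_normal(mu, lv).item() == 0.0
        mu2 = Tensor(np.full((2, 3, 4), 0.1))
        assert kl_standard_normal(mu2, lv).item() > 0

    def test_kl_closed_form_against_quadrature(self):
        """KL(N(mu,1) || N(0,1)) = mu^2/2 per dim, checked by integration."""
        mu = 0.7

        def integrand(x):
            q = np.exp(-(x - mu) ** 2 / 2) / np.sqrt(2 * np.pi)
            p = np.exp(-x ** 2 / 2) / np.sqrt(2 * np.pi)
            return q * np.log(q / p)

        quad, _ = integrate.quad(integrand, -12, 12)
        assert quad == pytest.approx(mu ** 2 / 2, abs=1e-9)
        got = kl_standard_normal(Tensor(np.full((1, 1, 1), mu)),
                                 Tensor(np.zeros((1, 1, 1)))).item()
        assert got == pytest.approx(quad, abs=1e-9)

    def test_beta_zero_reduces_to_reconstruction(self, rng, tiny_params):
        batch = rand_batch(rng)
        full = M.elbo_loss(batch, tiny_params, "C", beta_kl=1.0, seed=1).item()
        rec = M.elbo_loss(batch, tiny_params, "C", beta_kl=0.0, seed=1).item()
        mu, lv = tiny_params.encode_dist(batch.x_cont, "C")
        kl = kl_standard_normal(mu, lv).item()
        assert full == pytest.approx(rec + kl, rel=1e-10)


class TestMatchingLoss:
    def test_zero_at_identity_and_joint_permutation_invariance(self, rng):
        z = rng.normal(size=(5, 4, 3))
        assert M.matching_loss(M.LatentSeriesBatch(z, z)).item() == 0.0
        z2 = rng.normal(size=(5, 4, 3))
        perm = rng.permutation(5)
        a = M.matching_loss(M.LatentSeriesBatch(z, z2)).item()
        b = M.matching_loss(M.LatentSeriesBatch(z[perm], z2[perm])).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_offset_hand_value(self, rng):
        z = rng.normal(size=(5, 4, 3))
        c = 0.7
        got = M.matching_loss(M.LatentSeriesBatch(z, z + c)).item()
        assert got == pytest.approx(4 * 3 * c ** 2, rel=1e-12)


def _ntxent_bruteforce(hc, hd, tau):
    """Direct double-loop NT-Xent (independent oracle)."""
    h = np.concatenate([hc, hd], axis=0)
    h = h / np.linalg.norm(h, axis=1, keepdims=True)
    n2 = len(h)
    n = n2 // 2
    sim = h @ h.T / tau
    total = 0.0
    for i in range(n):
        for (a, b) in ((i, i + n), (i + n, i)):
            denom = sum(np.exp(sim[a, j]) for j in range(n2) if j != a)
            total += -np.log(np.exp(sim[a, b]) / denom)
    return total / n2


class TestContrastiveLoss:
    def test_matches_bruteforce(self, rng):
        hc = rng.normal(size=(2, 4))
        hd = rng.normal(size=(2, 4))
        got = M.contrastive_loss(hc, hd, tau=0.5).item()
        assert got == pytest.approx(_ntxent_bruteforce(hc, hd, 0.5), abs=1e-10)
        hc5, hd5 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        got5 = M.contrastive_loss(hc5, hd5, tau=0.7).item()
        assert got5 == pytest.approx(_ntxent_bruteforce(hc5, hd5, 0.7), abs=1e-10)

    def test_identical_embeddings_closed_form(self):
        h = np.tile(np.array([[1.0, 2.0, -1.0]]), (4, 1))
        got = M.contrastive_loss(h, h, tau=0.5).item()
        assert got == pytest.approx(np.log(2 * 4 - 1), abs=1e-10)

    def test_positive_scale_invariance(self, rng):
        hc, hd = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        a = M.contrastive_loss(hc, hd, tau=0.5).item()
        b = M.contrastive_loss(3.7 * hc, 3.7 * hd, tau=0.5).item()
        assert a == pytest.approx(b, rel=1e-10)

    def test_zero_norm_embedding_rejected(self, rng):
        hc = rng.normal(size=(3, 4))
        hc[1] = 0.0
        with pytest.raises(ValueError, match="zero-norm"):
            M.contrastive_loss(hc, rng.normal(size=(3, 4)))


class TestSemanticLoss:
    def test_uniform_prediction_gives_log_L(self, rng):
        clf = nn.Linear(rng, 4, 3)
        clf.W.data[...] = 0.0
        clf.b.data[...] = 0.0
        labels = np.eye(3)[rng.integers(3, size=6)]
        got = semantic_loss(rng.normal(size=(6, 4)), labels, clf).item()
        assert got == pytest.approx(np.log(3), abs=1e-12)

    def test_matches_independent_cross_entropy(self, rng):
        clf = nn.Linear(rng, 4, 3)
        h = rng.normal(size=(6, 4))
        labels = np.eye(3)[rng.integers(3, size=6)]
        logits = h @ clf.W.data + clf.b.data
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        expect = -np.mean(np.log(p[labels.astype(bool)]))
        assert semantic_loss(h, labels, clf).item() == pytest.approx(
            expect, rel=1e-10)

    def test_missing_labels_instructs_nonconditional(self, rng):
        clf = nn.Linear(rng, 4, 3)
        with pytest.raises(ValueError, match="non-conditional"):
            semantic_loss(rng.normal(size=(6, 4)), None, clf)


class TestPretrain:
    def test_decoupled_ablation_has_independent_gradients(self, rng):
        """With matching/contrastive off and no tying, domain C's loss has
        zero gradient w.r.t. every domain-D parameter."""
        batch = rand_batch(rng, n=8)
        cfg = M.VAEConfig(hidden=8, latent_dim=2, tie_weights=False)
        params = VAEParams(rng, batch.dim_cont, batch.dim_disc, cfg)
        loss = M.elbo_loss(batch, params, "C", seed=0)
        for p in params.parameters():
            p.grad = None
        loss.backward()
        d_params = (params.enc_rnn["D"].parameters()
                    + params.mu_head["D"].parameters()
                    + params.lv_head["D"].parameters()
                    + params.dec_proj["D"].parameters()
                    + params.dec_rnn["D"].parameters()
                    + params.dec_head["D"].parameters())
        assert all(p.grad is None for p in d_params)
        c_params = params.enc_rnn["C"].parameters()
        assert all(p.grad is not None for p in c_params)

    def test_loss_decreases_and_is_reproducible(self):
        batch = M.simulate_batch(M.SimulatorConfig(n_patients=48, seed=2))
        cfg = M.VAEConfig(hidden=8, latent_dim=2, batch_size=16)
        # fixed objective (no KL anneal) so the curve is comparable across epochs
        p1, c1 = M.pretrain(batch, M.LossWeights(), cfg, epochs=10, seed=5,
                            kl_warmup_frac=0.0)
        p2, c2 = M.pretrain(batch, M.LossWeights(), cfg, epochs=10, seed=5,
                            kl_warmup_frac=0.0)
        assert c1["total"] == c2["total"]
        for a, b in zip(p1.parameters(), p2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        # decreasing in moving average over epochs
        tot = np.asarray(c1["total"])
        assert tot[-3:].mean() < tot[:3].mean()

    def test_weight_tie_invariant_after_training(self, small_batch, pretrained):
        vae, _ = pretrained
        for a, b in vae.tied_pairs():
            assert a is b or np.array_equal(a.data, b.data)

    def test_reconstruction_error_within_noise_bound(self, small_batch,
                                                     pretrained):
        """Posterior-mean reconstruction RMSE of the continuous channels is
        at most twice the simulator's observation noise SD."""
        vae, _ = pretrained
        lat = M.encode(small_batch, vae, sample=False)
        xc, _ = M.decode(lat, vae)
        rmse = np.sqrt(((xc - small_batch.x_cont) ** 2).mean())
        assert rmse <= 2 * 0.5

    def test_paired_latents_closer_than_random_pairs(self, small_batch,
                                                     pretrained):
        """Same-patient z^C/z^D pairs are closer than cross-patient pairs —
        the literal claim of the matching/contrastive objectives."""
        vae, _ = pretrained
        lat = M.encode(small_batch, vae, sample=False)
        hc, hd = lat.z_cont.mean(axis=1), lat.z_disc.mean(axis=1)
        same = ((hc - hd) ** 2).sum(axis=1).mean()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(hd))
        while np.any(perm == np.arange(len(hd))):
            perm = rng.permutation(len(hd))
        cross = ((hc - hd[perm]) ** 2).sum(axis=1).mean()
        assert same < cross

    def test_divergence_aborts_with_epoch(self, rng):
        batch = rand_batch(rng, n=16, T=4)
        cfg = M.VAEConfig(hidden=8, latent_dim=2, lr=1e6, batch_size=8)
        with pytest.raises(RuntimeError, match="epoch"):
            M.pretrain(batch, M.LossWeights(), cfg, epochs=30, seed=0)
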