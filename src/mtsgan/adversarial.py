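"""Adversarial training of the coupled generator against per-type critics.

Generated samples are produced by decoding the coupled generator's latent
trajectories with the *pretrained* decoders (frozen by default, so the
latent-to-observation mapping the discrete path relies on stays fixed).
One recurrent discriminator per data type scores whole sequences; the
discrete stream is scored on the decoder's Bernoulli probabilities during
training so the entire path stays differentiable — hard 0/1 thresholding
happens only at sampling time in :func:`generate`.

Losses are logit-based (softplus form) so the objective stays finite even
when a discriminator saturates; the generator minimizes the standard
non-saturating counterpart of the min-max value function, summed over both
domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat, stack
from .data import DatasetManifest, MixedSeriesBatch, unscale
from .dual_vae import LatentSeriesBatch, VAEParams
from .generator import BLSTMParams, NoiseBatch, generate_latents, sample_noise
from .dp import DPConfig, RDPAccountant, dp_step
from . import nn

ABLATIONS = ("full", "gan_vae", "gan_sl")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    lr_gen: float = 1e-3
    lr_disc: float = 1e-3
    disc_steps: int = 1
    gen_steps: int = 1
    hidden: int = 64
    noise_dim: Optional[int] = None      # defaults to the latent dim |S|
    decoder_finetune: bool = False
    ablation: str = "full"
    conditional: bool = False
    dp: Optional[DPConfig] = None
    seed: int = 0

    def __post_init__(self):
        if self.lr_gen <= 0 or self.lr_disc <= 0:
            raise ValueError("learning rates must be positive")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")


class DiscriminatorParams:
    """Per-domain LSTM sequence discriminators with sigmoid heads."""

    def __init__(self, rng: np.random.Generator, dim_cont: int, dim_disc: int,
                 hidden: int, n_labels: int = 0):
        self.hidden = hidden
        self.n_labels = n_labels
        self.rnn = {"C": nn.LSTM(rng, dim_cont + n_labels, hidden),
                    "D": nn.LSTM(rng, dim_disc + n_labels, hidden)}
        self.head = {"C": nn.Linear(rng, hidden, 1),
                     "D": nn.Linear(rng, hidden, 1)}

    def logit(self, x: Tensor, domain: str,
              labels: Optional[np.ndarray] = None) -> Tensor:
        if self.n_labels:
            if labels is None:
                raise ValueError("conditional discriminator requires labels")
            lab = np.repeat(labels[:, None, :], x.shape[1], axis=1)
            x = concat([x, Tensor(lab)], axis=-1)
        hs = self.rnn[domain](nn.split_timesteps(x))
        return self.head[domain](nn.sum_mean(hs))[:, 0]

    def score(self, x: np.ndarray, domain: str,
              labels: Optional[np.ndarray] = None) -> np.ndarray:
        """Probability-of-real per sequence, in (0, 1)."""
        return self.logit(Tensor(x), domain, labels).sigmoid().data

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for d in ("C", "D"):
            ps += self.rnn[d].parameters() + self.head[d].parameters()
        return ps


def _fake_batch(gen: BLSTMParams, vae: VAEParams, n: int, T: int,
                rng: np.random.Generator,
                labels: Optional[np.ndarray] = None) -> tuple[Tensor, Tensor]:
    """Differentiable synthetic pair (continuous values, discrete probs)."""
    seed = int(rng.integers(2 ** 31))
    noise = sample_noise(n, T, gen.noise_dim, seed=seed)
    zc, zd = generate_latents(noise, gen, labels=labels, as_tensors=True)
    xc = vae.decode_logits(zc, "C", labels)
    pd_ = vae.decode_logits(zd, "D", labels).sigmoid()
    return xc, pd_


def _disc_loss(disc: DiscriminatorParams, real: MixedSeriesBatch,
               fake_c: Tensor, fake_d: Tensor,
               labels_fake: Optional[np.ndarray]) -> Tensor:
    loss = None
    for domain, xr, xf in (("C", real.x_cont, fake_c), ("D", real.x_disc, fake_d)):
        lr_ = disc.logit(Tensor(xr), domain, real.labels)
        lf = disc.logit(xf, domain, labels_fake)
        # -log D(x) - log(1 - D(x_hat)), in logit form
        term = (-lr_).softplus().mean() + lf.softplus().mean()
        loss = term if loss is None else loss + term
    return loss


def _gen_loss(disc: DiscriminatorParams, fake_c: Tensor, fake_d: Tensor,
              labels_fake: Optional[np.ndarray]) -> Tensor:
    loss = None
    for domain, xf in (("C", fake_c), ("D", fake_d)):
        lf = disc.logit(xf, domain, labels_fake)
        term = (-lf).softplus().mean()       # non-saturating: -log D(x_hat)
        loss = term if loss is None else loss + term
    return loss


def _sample_labels(real: MixedSeriesBatch, n: int,
                   rng: np.random.Generator) -> Optional[np.ndarray]:
    if real.labels is None:
        return None
    rows = rng.integers(real.n, size=n)
    return real.labels[rows]


def train_gan(data: MixedSeriesBatch, vae: VAEParams, config: TrainConfig
              ) -> tuple[BLSTMParams, DiscriminatorParams, list[dict]]:
    """Alternating min-max training; returns generator, discriminators, log.

    Ablations: ``gan_vae`` and ``gan_sl`` pin the generator's cross-stream
    weights to zero after every update (the difference between the two lives
    in how the VAE was pretrained — independent vs shared-latent losses).
    """
    if config.dp is not None and config.decoder_finetune:
        raise ValueError("DP training with decoder fine-tuning is unsupported")
    rng = np.random.default_rng(config.seed)
    S = vae.config.latent_dim
    noise_dim = config.noise_dim or S
    n_labels = vae.config.n_labels if config.conditional else 0
    if config.conditional and data.labels is None:
        raise ValueError("conditional training requires labels")

    gen = BLSTMParams(rng, noise_dim, config.hidden, S, n_labels=n_labels)
    disc = DiscriminatorParams(rng, data.dim_cont, data.dim_disc,
                               config.hidden, n_labels=n_labels)
    uncoupled = config.ablation in ("gan_vae", "gan_sl")
    if uncoupled:
        gen.zero_cross_weights()

    gen_params = gen.parameters()
    if config.decoder_finetune:
        for d in ("C", "D"):
            gen_params += vae.dec_proj[d].parameters()
            gen_params += vae.dec_rnn[d].parameters()
            gen_params += vae.dec_head[d].parameters()
    opt_g = nn.Adam(nn.dedupe(gen_params), lr=config.lr_gen)
    opt_d = nn.Adam(disc.parameters(), lr=config.lr_disc)

    accountant = None
    if config.dp is not None:
        q = min(1.0, config.batch_size / data.n)
        accountant = RDPAccountant(q, config.dp.noise_multiplier)

    log: list[dict] = []
    T = data.T
    for epoch in range(config.epochs):
        d_losses, g_losses = [], []
        for idx in nn.minibatches(data.n, config.batch_size, rng):
            sub = data.subset(idx)
            # --- discriminator step(s)
            for _ in range(config.disc_steps):
                labels_fake = _sample_labels(sub, sub.n, rng) \
                    if config.conditional else None
                fake_c, fake_d = _fake_batch(gen, vae, sub.n, T, rng, labels_fake)
                if config.dp is None:
                    loss_d = _disc_loss(disc, sub, fake_c, fake_d, labels_fake)
                    opt_d.zero_grad()
                    loss_d.backward()
                    opt_d.step()
                    d_losses.append(loss_d.item())
                else:
                    loss_d = _dp_disc_update(disc, sub, fake_c, fake_d,
                                             labels_fake, config.dp, rng, opt_d)
                    accountant.step()
                    d_losses.append(loss_d)
            # --- generator step(s)
            for _ in range(config.gen_steps):
                labels_fake = _sample_labels(sub, sub.n, rng) \
                    if config.conditional else None
                fake_c, fake_d = _fake_batch(gen, vae, sub.n, T, rng, labels_fake)
                loss_g = _gen_loss(disc, fake_c, fake_d, labels_fake)
                opt_g.zero_grad()
                loss_g.backward()
                opt_g.step()
                if uncoupled:
                    gen.zero_cross_weights()
                g_losses.append(loss_g.item())
        rec = {"epoch": epoch, "loss_disc": float(np.mean(d_losses)),
               "loss_gen": float(np.mean(g_losses))}
        if accountant is not None:
            rec["epsilon"] = accountant.epsilon(config.dp.delta)
        log.append(rec)
        if not (np.isfinite(rec["loss_disc"]) and np.isfinite(rec["loss_gen"])):
            raise RuntimeError(f"adversarial training diverged at epoch {epoch}: {rec}")
        if (config.dp is not None and config.dp.target_epsilon is not None
                and rec["epsilon"] >= config.dp.target_epsilon):
            break
    return gen, disc, log


def _dp_disc_update(disc, sub, fake_c, fake_d, labels_fake, dp_cfg, rng, opt_d):
    """Per-sample clipped + noised discriminator update (DP-SGD)."""
    params = opt_d.params
    losses = []
    for i in range(sub.n):
        one = sub.subset(np.array([i]))
        lf = None
        fc_i = Tensor(fake_c.data[i:i + 1])   # fakes carry no real-data info
        fd_i = Tensor(fake_d.data[i:i + 1])
        li = labels_fake[i:i + 1] if labels_fake is not None else None
        losses.append(_disc_loss(disc, one, fc_i, fd_i, li))
    norms = dp_step(params, losses, dp_cfg, rng, opt_d)
    if norms.max() > dp_cfg.clip_norm + 1e-9:
        raise AssertionError("clipping contract violated")
    return float(np.mean([l.item() for l in losses]))


def dp_train_gan(data: MixedSeriesBatch, vae: VAEParams, config: TrainConfig
                 ) -> tuple[BLSTMParams, DiscriminatorParams, list[dict], dict]:
    """DP variant: discriminator updates run under DP-SGD; returns the
    privacy report (achieved epsilon at delta) alongside the training log."""
    if config.dp is None:
        raise ValueError("dp_train_gan requires config.dp")
    gen, disc, log = train_gan(data, vae, config)
    eps = log[-1].get("epsilon", 0.0) if log else 0.0
    if not np.isfinite(eps):
        raise RuntimeError("accountant reports epsilon = inf (degenerate settings)")
    report = {"epsilon": eps, "delta": config.dp.delta,
              "noise_multiplier": config.dp.noise_multiplier,
              "clip_norm": config.dp.clip_norm, "steps": len(log)}
    return gen, disc, log, report


def generate(n: int, vae: VAEParams, gen: BLSTMParams,
             labels: Optional[np.ndarray] = None, seed: int = 0,
             manifest: Optional[DatasetManifest] = None,
             bernoulli: bool = False,
             feature_names_cont: Optional[list[str]] = None,
             feature_names_disc: Optional[list[str]] = None,
             T: int = 24) -> MixedSeriesBatch:
    """Sample n synthetic records: noise -> latents -> decode -> threshold.

    Discrete probabilities are thresholded at 0.5 by default (Bernoulli
    sampling behind ``bernoulli=True``); continuous output is mapped back to
    original units when the manifest carries scaling statistics.
    """
    if labels is not None and not gen.n_labels:
        raise ValueError("labels given to an unconditional model")
    if gen.n_labels and labels is None:
        raise ValueError("conditional model requires labels")
    rng = np.random.default_rng(seed)
    if manifest is not None:
        T = manifest.T
        feature_names_cont = feature_names_cont or manifest.feature_names_cont
        feature_names_disc = feature_names_disc or manifest.feature_names_disc
    if feature_names_cont is None:
        feature_names_cont = [f"cont_{j}" for j in range(vae.dim_cont)]
    if feature_names_disc is None:
        feature_names_disc = [f"disc_{k}" for k in range(vae.dim_disc)]

    if n == 0:
        return MixedSeriesBatch(
            x_cont=np.zeros((0, T, vae.dim_cont)),
            x_disc=np.zeros((0, T, vae.dim_disc)), labels=labels,
            feature_names_cont=feature_names_cont,
            feature_names_disc=feature_names_disc)

    noise = sample_noise(n, T, gen.noise_dim, seed=int(rng.integers(2 ** 31)))
    zc, zd = generate_latents(noise, gen, labels=labels, as_tensors=True)
    x_cont = vae.decode_logits(zc, "C", labels).data
    p_disc = vae.decode_logits(zd, "D", labels).sigmoid().data
    if bernoulli:
        x_disc = (rng.uniform(size=p_disc.shape) < p_disc).astype(float)
    else:
        x_disc = (p_disc >= 0.5).astype(float)
    if manifest is not None:
        x_cont = unscale(x_cont, manifest)
    return MixedSeriesBatch(x_cont=x_cont, x_disc=x_disc, labels=labels,
                            feature_names_cont=feature_names_cont,
                            feature_names_disc=feature_names_disc)
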