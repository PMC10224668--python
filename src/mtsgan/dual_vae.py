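"""Dual recurrent VAEs sharing one latent space.

Pretraining stage of the pipeline: a continuous-channel VAE and a
discrete-channel VAE encode the two halves of each patient's record into
per-timestep Gaussian posteriors in the *same* latent space H^S.  Four loss
terms shape that space:

* ELBO per domain — unit-variance Gaussian likelihood for the continuous
  channels (reconstruction = squared error), Bernoulli likelihood for the
  binary channels (reconstruction = cross-entropy), closed-form KL against
  the N(0, I) prior.
* matching loss — squared distance between the paired per-timestep latents
  of the same patient (instance-level alignment).
* contrastive loss — NT-Xent over the 2N temporally mean-pooled embeddings,
  positive pair = the two views of one patient (population-level alignment).
* semantic loss (conditional mode) — cross-entropy of a linear classifier
  predicting the condition label from the pooled latent.

A weight-sharing constraint ties the latent-adjacent layers across domains:
the posterior mean/log-variance heads of the two encoders and the latent
input projection of the two decoders are the same parameter objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat, stack
from .data import MixedSeriesBatch
from . import nn


@dataclass
class LossWeights:
    """Scalar weights balancing the pretraining loss terms."""

    beta_kl: float = 1.0
    beta0: float = 1.0   # ELBO
    beta1: float = 1.0   # matching
    beta2: float = 0.1   # contrastive
    beta3: float = 0.1   # semantic (conditional mode)
    tau: float = 0.5     # NT-Xent temperature

    def __post_init__(self):
        for name in ("beta_kl", "beta0", "beta1", "beta2", "beta3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class VAEConfig:
    latent_dim: int = 4
    hidden: int = 64
    tie_weights: bool = True
    conditional: bool = False
    n_labels: int = 0
    lr: float = 1e-3
    batch_size: int = 128


@dataclass
class LatentSeriesBatch:
    """Paired latent trajectories of the two domains, N x T x |S| each."""

    z_cont: np.ndarray
    z_disc: np.ndarray

    def __post_init__(self):
        self.z_cont = np.asarray(self.z_cont, dtype=np.float64)
        self.z_disc = np.asarray(self.z_disc, dtype=np.float64)
        if self.z_cont.shape != self.z_disc.shape:
            raise ValueError("paired latent tensors must share N, T, |S|")
        if not (np.isfinite(self.z_cont).all() and np.isfinite(self.z_disc).all()):
            raise ValueError("latents must be finite")

    @property
    def latent_dim(self) -> int:
        return self.z_cont.shape[2]


class VAEParams:
    """Encoder/decoder parameters for both domains with tied latent layers."""

    def __init__(self, rng: np.random.Generator, dim_cont: int, dim_disc: int,
                 config: VAEConfig):
        self.config = config
        S, H = config.latent_dim, config.hidden
        nl = config.n_labels if config.conditional else 0
        self.enc_rnn = {"C": nn.LSTM(rng, dim_cont + nl, H),
                        "D": nn.LSTM(rng, dim_disc + nl, H)}
        # tied posterior heads (latent-adjacent encoder layers)
        mu_head = nn.Linear(rng, H, S)
        lv_head = nn.Linear(rng, H, S)
        if config.tie_weights:
            self.mu_head = {"C": mu_head, "D": mu_head}
            self.lv_head = {"C": lv_head, "D": lv_head}
        else:
            self.mu_head = {"C": mu_head, "D": nn.Linear(rng, H, S)}
            self.lv_head = {"C": lv_head, "D": nn.Linear(rng, H, S)}
        # tied decoder input projection (latent-adjacent decoder layer)
        proj = nn.Linear(rng, S, H)
        if config.tie_weights:
            self.dec_proj = {"C": proj, "D": proj}
        else:
            self.dec_proj = {"C": proj, "D": nn.Linear(rng, S, H)}
        self.dec_rnn = {"C": nn.LSTM(rng, H + nl, H),
                        "D": nn.LSTM(rng, H + nl, H)}
        self.dec_head = {"C": nn.Linear(rng, H, dim_cont),
                         "D": nn.Linear(rng, H, dim_disc)}
        self.classifier = None
        if config.conditional:
            self.classifier = {"C": nn.Linear(rng, S, config.n_labels),
                               "D": nn.Linear(rng, S, config.n_labels)}
        self.dim_cont, self.dim_disc = dim_cont, dim_disc

    # -- forward passes -----------------------------------------------------
    def _domain_input(self, x: np.ndarray, labels: Optional[np.ndarray]) -> Tensor:
        xt = Tensor(x)
        if self.config.conditional:
            if labels is None:
                raise ValueError("conditional mode requires labels")
            lab = np.repeat(labels[:, None, :], x.shape[1], axis=1)
            xt = concat([xt, Tensor(lab)], axis=-1)
        return xt

    def encode_dist(self, x: np.ndarray, domain: str,
                    labels: Optional[np.ndarray] = None) -> tuple[Tensor, Tensor]:
        """Per-timestep posterior mean and log-variance, each N x T x |S|."""
        xt = self._domain_input(x, labels)
        hs = self.enc_rnn[domain](nn.split_timesteps(xt))
        mu = stack([self.mu_head[domain](h) for h in hs], axis=1)
        lv = stack([self.lv_head[domain](h) for h in hs], axis=1)
        return mu, lv

    def decode_domain(self, z: Tensor, domain: str,
                      labels: Optional[np.ndarray] = None) -> Tensor:
        """Decode latent trajectories; returns values (C) or probabilities (D)
        when ``domain`` dictates; the raw head output is returned for C and
        logits for D via :meth:`decode_logits`."""
        return self.decode_logits(z, domain, labels) if domain == "C" else \
            self.decode_logits(z, domain, labels).sigmoid()

    def decode_logits(self, z: Tensor, domain: str,
                      labels: Optional[np.ndarray] = None) -> Tensor:
        n, T, _ = z.shape
        proj = self.dec_proj[domain](z).tanh()
        if self.config.conditional:
            if labels is None:
                raise ValueError("conditional mode requires labels")
            lab = np.repeat(labels[:, None, :], T, axis=1)
            proj = concat([proj, Tensor(lab)], axis=-1)
        hs = self.dec_rnn[domain](nn.split_timesteps(proj))
        return stack([self.dec_head[domain](h) for h in hs], axis=1)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for d in ("C", "D"):
            ps += self.enc_rnn[d].parameters() + self.mu_head[d].parameters()
            ps += self.lv_head[d].parameters() + self.dec_proj[d].parameters()
            ps += self.dec_rnn[d].parameters() + self.dec_head[d].parameters()
            if self.classifier is not None:
                ps += self.classifier[d].parameters()
        return nn.dedupe(ps)

    def tied_pairs(self) -> list[tuple[Tensor, Tensor]]:
        """Pairs that the weight-sharing constraint requires bit-identical."""
        if not self.config.tie_weights:
            return []
        return [(self.mu_head["C"].W, self.mu_head["D"].W),
                (self.lv_head["C"].W, self.lv_head["D"].W),
                (self.dec_proj["C"].W, self.dec_proj["D"].W)]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def reparameterize(mu: Tensor, logvar: Tensor,
                   rng: np.random.Generator) -> Tensor:
    eps = rng.standard_normal(mu.shape)
    return mu + (logvar * 0.5).exp() * Tensor(eps)


def kl_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """Closed-form KL( N(mu, diag e^logvar) || N(0, I) ), summed over time
    and latent dims, averaged over the batch."""
    per = 0.5 * (mu ** 2 + logvar.exp() - logvar - 1.0)
    return per.sum(axis=(1, 2)).mean()


def elbo_loss(batch: MixedSeriesBatch, params: VAEParams, domain: str,
              beta_kl: float = 1.0, rng: Optional[np.random.Generator] = None,
              seed: int = 0) -> Tensor:
    """Negative ELBO for one domain (lower is better)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    x = batch.x_cont if domain == "C" else batch.x_disc
    mu, lv = params.encode_dist(x, domain, batch.labels)
    z = reparameterize(mu, lv, rng)
    if domain == "C":
        recon = params.decode_logits(z, "C", batch.labels)
        nll = (0.5 * (recon - Tensor(x)) ** 2).sum(axis=(1, 2)).mean()
    else:
        logits = params.decode_logits(z, "D", batch.labels)
        nll = nn.bce_with_logits(logits, x).sum(axis=(1, 2)).mean()
    return nll + beta_kl * kl_standard_normal(mu, lv)


def matching_loss(latents) -> Tensor:
    """Mean over patients of sum_t ||z^C_t - z^D_t||^2."""
    zc = latents.z_cont if isinstance(latents, LatentSeriesBatch) else latents[0]
    zd = latents.z_disc if isinstance(latents, LatentSeriesBatch) else latents[1]
    zc = zc if isinstance(zc, Tensor) else Tensor(zc)
    zd = zd if isinstance(zd, Tensor) else Tensor(zd)
    if zc.shape != zd.shape:
        raise ValueError("paired latents must share shape")
    return ((zc - zd) ** 2).sum(axis=(1, 2)).mean()


def contrastive_loss(h_cont, h_disc, tau: float = 0.5) -> Tensor:
    """NT-Xent over the 2N pooled embeddings (both pairings averaged)."""
    hc = h_cont if isinstance(h_cont, Tensor) else Tensor(h_cont)
    hd = h_disc if isinstance(h_disc, Tensor) else Tensor(h_disc)
    n = hc.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 records")
    if (np.linalg.norm(hc.data, axis=1) < 1e-300).any() or \
       (np.linalg.norm(hd.data, axis=1) < 1e-300).any():
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    h = concat([hc, hd], axis=0)                         # 2N x S
    norm = (h ** 2).sum(axis=1, keepdims=True).sqrt()
    hn = h / norm
    sim = (hn @ hn.transpose(1, 0)) * (1.0 / tau)        # 2N x 2N
    # mask self-similarity out of the denominator
    eye = np.eye(2 * n)
    masked = sim + Tensor(-1e30 * eye)
    from .autodiff import logsumexp
    denom = logsumexp(masked, axis=1)                    # 2N
    pos_idx = np.concatenate([np.arange(n, 2 * n), np.arange(0, n)])
    pos = sim[np.arange(2 * n), pos_idx]
    return (denom - pos).mean()


def semantic_loss(latent_summary, labels: np.ndarray,
                  classifier: nn.Linear) -> Tensor:
    """Cross-entropy of a linear head on per-patient latent summaries."""
    if labels is None:
        raise ValueError("labels required: run in non-conditional mode otherwise")
    hs = latent_summary if isinstance(latent_summary, Tensor) else Tensor(latent_summary)
    return nn.softmax_cross_entropy(classifier(hs), labels)


def pooled(z: Tensor) -> Tensor:
    """Temporal mean over an N x T x S latent trajectory."""
    return z.mean(axis=1)


# ---------------------------------------------------------------------------
# encode / decode public API
# ---------------------------------------------------------------------------

def encode(batch: MixedSeriesBatch, params: VAEParams, sample: bool = False,
           seed: int = 0) -> LatentSeriesBatch:
    rng = np.random.default_rng(seed)
    out = {}
    for domain, x in (("C", batch.x_cont), ("D", batch.x_disc)):
        mu, lv = params.encode_dist(x, domain, batch.labels)
        z = reparameterize(mu, lv, rng) if sample else mu
        out[domain] = z.data
    return LatentSeriesBatch(z_cont=out["C"], z_disc=out["D"])


def decode(latents: LatentSeriesBatch, params: VAEParams,
           labels: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructions: continuous values N x T x |J| and discrete Bernoulli
    probabilities N x T x |K| in (0,1)."""
    xc = params.decode_logits(Tensor(latents.z_cont), "C", labels).data
    pd_ = params.decode_logits(Tensor(latents.z_disc), "D", labels).sigmoid().data
    return xc, pd_


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def pretrain(batch: MixedSeriesBatch, weights: LossWeights = LossWeights(),
             config: VAEConfig = None, epochs: int = 50,
             seed: int = 0, kl_warmup_frac: float = 0.5
             ) -> tuple[VAEParams, dict[str, list[float]]]:
    """Joint pretraining of both VAEs; returns parameters and loss curves.

    The optimized objective counts the shared matching/contrastive terms
    once:  beta0*(ELBO_C + ELBO_D) + beta1*Match + beta2*Contra
    (+ beta3*(Class_C + Class_D) in conditional mode).

    The KL weight is linearly annealed from 0 to ``weights.beta_kl`` over
    the first ``kl_warmup_frac`` of the epochs — the standard counter to
    posterior collapse in recurrent VAEs, where an early strong prior pull
    teaches the decoders to ignore their latents (the binary channels, with
    their small reconstruction term, are especially prone to it).
    """
    config = config or VAEConfig()
    if config.conditional:
        if batch.labels is None:
            raise ValueError("conditional pretraining requires labels")
        config.n_labels = batch.labels.shape[1]
    rng = np.random.default_rng(seed)
    params = VAEParams(rng, batch.dim_cont, batch.dim_disc, config)
    opt = nn.Adam(params.parameters(), lr=config.lr)

    curves: dict[str, list[float]] = {k: [] for k in
                                      ("total", "elbo_C", "elbo_D", "match",
                                       "contra", "class_C", "class_D")}
    warm_epochs = max(1, int(round(kl_warmup_frac * epochs)))
    for epoch in range(epochs):
        anneal = min(1.0, epoch / warm_epochs) if kl_warmup_frac > 0 else 1.0
        eff = replace_kl(weights, weights.beta_kl * anneal)
        ep = {k: 0.0 for k in curves}
        nb = 0
        for idx in nn.minibatches(batch.n, config.batch_size, rng):
            sub = batch.subset(idx)
            loss, parts = _pretrain_loss(sub, params, eff, config, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"pretraining diverged at epoch {epoch}")
            for k, v in parts.items():
                ep[k] += v
            nb += 1
        for k in curves:
            curves[k].append(ep[k] / nb)
    return params, curves


def replace_kl(weights: LossWeights, beta_kl: float) -> LossWeights:
    from dataclasses import replace
    return replace(weights, beta_kl=beta_kl)


def _pretrain_loss(sub: MixedSeriesBatch, params: VAEParams,
                   weights: LossWeights, config: VAEConfig,
                   rng: np.random.Generator):
    mu_c, lv_c = params.encode_dist(sub.x_cont, "C", sub.labels)
    mu_d, lv_d = params.encode_dist(sub.x_disc, "D", sub.labels)
    z_c = reparameterize(mu_c, lv_c, rng)
    z_d = reparameterize(mu_d, lv_d, rng)

    rec_c = params.decode_logits(z_c, "C", sub.labels)
    nll_c = (0.5 * (rec_c - Tensor(sub.x_cont)) ** 2).sum(axis=(1, 2)).mean()
    elbo_c = nll_c + weights.beta_kl * kl_standard_normal(mu_c, lv_c)

    logit_d = params.decode_logits(z_d, "D", sub.labels)
    nll_d = nn.bce_with_logits(logit_d, sub.x_disc).sum(axis=(1, 2)).mean()
    elbo_d = nll_d + weights.beta_kl * kl_standard_normal(mu_d, lv_d)

    loss = weights.beta0 * (elbo_c + elbo_d)
    parts = {"elbo_C": elbo_c.item(), "elbo_D": elbo_d.item(),
             "match": 0.0, "contra": 0.0, "class_C": 0.0, "class_D": 0.0}

    if weights.beta1 > 0:
        match = matching_loss((mu_c, mu_d))
        loss = loss + weights.beta1 * match
        parts["match"] = match.item()
    if weights.beta2 > 0:
        contra = contrastive_loss(pooled(mu_c), pooled(mu_d), weights.tau)
        loss = loss + weights.beta2 * contra
        parts["contra"] = contra.item()
    if config.conditional and weights.beta3 > 0:
        cls_c = semantic_loss(pooled(mu_c), sub.labels, params.classifier["C"])
        cls_d = semantic_loss(pooled(mu_d), sub.labels, params.classifier["D"])
        loss = loss + weights.beta3 * (cls_c + cls_d)
        parts["class_C"] = cls_c.item()
        parts["class_D"] = cls_d.item()
    parts["total"] = loss.item()
    return loss, parts
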