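"""Differentially private SGD primitives and an RDP accountant.

DP-SGD bounds each record's influence by clipping its gradient to L2 norm
at most C, then adding Gaussian noise with standard deviation
``noise_multiplier * C`` to the summed gradient.  Privacy is tracked in
Renyi differential privacy (RDP) for the Poisson-subsampled Gaussian
mechanism at integer orders, composed over steps and converted to
(epsilon, delta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .autodiff import Tensor

DEFAULT_ORDERS = tuple(range(2, 65))


@dataclass
class DPConfig:
    clip_norm: float
    noise_multiplier: float
    delta: float = 1e-3
    target_epsilon: Optional[float] = None

    def __post_init__(self):
        if self.clip_norm <= 0 or self.noise_multiplier <= 0:
            raise ValueError("clip_norm and noise_multiplier must be positive")
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")


def rdp_subsampled_gaussian(q: float, sigma: float,
                            orders: Sequence[int] = DEFAULT_ORDERS) -> np.ndarray:
    """Per-step RDP of the sampled Gaussian mechanism at integer orders.

    Uses the binomial-expansion upper bound
    RDP(a) = log( sum_k C(a,k) (1-q)^(a-k) q^k exp((k^2-k)/(2 sigma^2)) ) / (a-1).
    """
    if not (0 < q <= 1):
        raise ValueError("sampling rate q must be in (0, 1]")
    if sigma <= 0:
        return np.full(len(orders), np.inf)
    out = np.empty(len(orders))
    for i, a in enumerate(orders):
        if q == 1.0:  # no subsampling: plain Gaussian mechanism, a/(2 sigma^2)
            out[i] = a / (2.0 * sigma ** 2)
            continue
        ks = np.arange(a + 1)
        log_terms = (gammaln(a + 1) - gammaln(ks + 1) - gammaln(a - ks + 1)
                     + (a - ks) * np.log1p(-q) + ks * np.log(q)
                     + (ks * ks - ks) / (2.0 * sigma ** 2))
        out[i] = logsumexp(log_terms) / (a - 1)
    return out


def epsilon_from_rdp(steps: int, q: float, sigma: float, delta: float,
                     orders: Sequence[int] = DEFAULT_ORDERS) -> float:
    """Achieved epsilon at the given delta after ``steps`` compositions."""
    if steps <= 0:
        return 0.0
    rdp = steps * rdp_subsampled_gaussian(q, sigma, orders)
    eps = rdp + np.log(1.0 / delta) / (np.asarray(orders) - 1)
    return float(np.min(eps))


class RDPAccountant:
    """Tracks privacy expenditure of repeated subsampled-Gaussian steps."""

    def __init__(self, sampling_rate: float, noise_multiplier: float,
                 orders: Sequence[int] = DEFAULT_ORDERS):
        self.q = sampling_rate
        self.sigma = noise_multiplier
        self.orders = tuple(orders)
        self._per_step = rdp_subsampled_gaussian(self.q, self.sigma, self.orders)
        self.steps = 0

    def step(self, n: int = 1) -> None:
        self.steps += n

    def epsilon(self, delta: float) -> float:
        if self.steps == 0:
            return 0.0
        rdp = self.steps * self._per_step
        eps = rdp + np.log(1.0 / delta) / (np.asarray(self.orders) - 1)
        return float(np.min(eps))


def clip_gradients(per_sample: Iterable[list[np.ndarray]],
                   clip_norm: float) -> tuple[list[np.ndarray], np.ndarray]:
    """Clip each sample's flattened gradient to L2 norm <= clip_norm.

    ``per_sample`` is a list (over samples) of per-parameter gradient lists.
    Returns the per-parameter *sum* of clipped gradients plus the post-clip
    norms (for the clipping contract check).
    """
    per_sample = list(per_sample)
    if not per_sample:
        raise ValueError("no per-sample gradients")
    sums = [np.zeros_like(g) for g in per_sample[0]]
    norms = np.empty(len(per_sample))
    for i, grads in enumerate(per_sample):
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
        scale = min(1.0, clip_norm / max(norm, 1e-12))
        norms[i] = norm * scale
        for s, g in zip(sums, grads):
            s += scale * g
    return sums, norms


def noisy_mean_gradients(sums: list[np.ndarray], n: int, clip_norm: float,
                         noise_multiplier: float,
                         rng: np.random.Generator) -> list[np.ndarray]:
    sd = noise_multiplier * clip_norm
    return [(s + rng.normal(0.0, sd, size=s.shape)) / n for s in sums]


def dp_step(params: list[Tensor], per_sample_losses, dp: DPConfig,
            rng: np.random.Generator, optimizer) -> np.ndarray:
    """One DP-SGD update: backprop each sample's loss separately, clip,
    noise, average, then let ``optimizer`` apply the update.

    ``per_sample_losses`` is a list of scalar Tensors, one per record.
    Returns the post-clip per-sample norms.
    """
    grads = []
    for loss in per_sample_losses:
        for p in params:
            p.grad = None
        loss.backward()
        grads.append([p.grad.copy() if p.grad is not None else
                      np.zeros_like(p.data) for p in params])
    sums, norms = clip_gradients(grads, dp.clip_norm)
    noisy = noisy_mean_gradients(sums, len(grads), dp.clip_norm,
                                 dp.noise_multiplier, rng)
    for p, g in zip(params, noisy):
        p.grad = g
    optimizer.step()
    return norms
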