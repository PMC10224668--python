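"""Recurrent building blocks and optimizers on top of :mod:`mtsgan.autodiff`.

Contains exactly the layers the synthesis pipeline needs: dense layers,
an LSTM cell/stack (encoders, decoders, discriminators, critics) and the
Adam optimizer.  Weight tying is expressed by letting two layers hold the
*same* :class:`~mtsgan.autodiff.Tensor` object; the optimizer de-duplicates
parameters by identity so a tied weight receives the summed gradient and a
single update, keeping the tied copies bit-identical by construction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .autodiff import Tensor, concat


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 weight: Tensor | None = None, bias: Tensor | None = None):
        self.W = weight if weight is not None else Tensor(glorot(rng, n_in, n_out),
                                                          requires_grad=True)
        self.b = bias if bias is not None else Tensor(np.zeros(n_out),
                                                      requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class LSTMCell:
    """Standard LSTM cell; gate order in the fused weight is (i, f, o, g)."""

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        self.hidden = hidden
        self.Wx = Tensor(glorot(rng, n_in, 4 * hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, hidden, 4 * hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden
        z = x @ self.Wx + h @ self.Wh + self.b
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        o = z[:, 2 * H:3 * H].sigmoid()
        g = z[:, 3 * H:4 * H].tanh()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


class LSTM:
    """Unidirectional LSTM unrolled over a batch-first sequence N x T x F."""

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        self.cell = LSTMCell(rng, n_in, hidden)
        self.hidden = hidden

    def __call__(self, xs: Sequence[Tensor], reverse: bool = False) -> list[Tensor]:
        """Run over a list of T tensors of shape N x F; returns T hidden states."""
        n = xs[0].shape[0]
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor] = [None] * len(xs)  # type: ignore[list-item]
        for t in order:
            h, c = self.cell(xs[t], h, c)
            out[t] = h
        return out

    def parameters(self) -> list[Tensor]:
        return self.cell.parameters()


def split_timesteps(x: Tensor) -> list[Tensor]:
    """View an N x T x F tensor as a list of T tensors N x F."""
    return [x[:, t, :] for t in range(x.shape[1])]


class BiLSTMClassifier:
    """Single-layer bidirectional LSTM with a linear head on mean-pooled states.

    Used both as the post-hoc discriminative-score critic (sigmoid head,
    ``n_out=1``) and, in unidirectional form elsewhere, mirrored by
    :class:`LSTMClassifier`.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int, n_out: int):
        self.fwd = LSTM(rng, n_in, hidden)
        self.bwd = LSTM(rng, n_in, hidden)
        self.head = Linear(rng, 2 * hidden, n_out)

    def logits(self, x: Tensor) -> Tensor:
        xs = split_timesteps(x)
        hf = self.fwd(xs)
        hb = self.bwd(xs, reverse=True)
        pooled = concat([sum_mean(hf), sum_mean(hb)], axis=-1)
        return self.head(pooled)

    def parameters(self) -> list[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters() + self.head.parameters()


class LSTMClassifier:
    """Unidirectional LSTM + linear head on the last hidden state."""

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int, n_out: int):
        self.rnn = LSTM(rng, n_in, hidden)
        self.head = Linear(rng, hidden, n_out)

    def logits(self, x: Tensor) -> Tensor:
        hs = self.rnn(split_timesteps(x))
        return self.head(hs[-1])

    def parameters(self) -> list[Tensor]:
        return self.rnn.parameters() + self.head.parameters()


def sum_mean(states: Sequence[Tensor]) -> Tensor:
    out = states[0]
    for s in states[1:]:
        out = out + s
    return out * (1.0 / len(states))


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy of logits (N x L) against one-hot rows."""
    from .autodiff import logsumexp
    lse = logsumexp(logits, axis=-1)
    picked = (logits * Tensor(onehot)).sum(axis=-1)
    return (lse - picked).mean()


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy; returns same-shape Tensor."""
    # softplus(l) - y*l  ==  -[y log s(l) + (1-y) log(1-s(l))]
    return logits.softplus() - logits * Tensor(target)


def dedupe(params: Iterable[Tensor]) -> list[Tensor]:
    seen: set[int] = set()
    out: list[Tensor] = []
    for p in params:
        if id(p) not in seen:
            seen.add(id(p))
            out.append(p)
    return out


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dedupe(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator,
                shuffle: bool = True):
    idx = np.arange(n)
    if shuffle:
        rng.shuffle(idx)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]
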