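"""Sequentially coupled generator: two bilateral-LSTM streams.

A bilateral LSTM (BLSTM) cell is an LSTM whose four gates additionally
receive the *previous hidden state of the counterpart stream*: gate g of
domain d at time t sees (noise_t^d, h_{t-1}^{d'}, h_{t-1}^d).  Two such
streams — one per data type — unrolled from zero state over paired uniform
noise sequences, followed by per-domain linear output projections, form the
coupled recurrent network that emits paired synthetic latent trajectories.
Zeroing the cross-stream weights reduces each stream exactly to a vanilla
LSTM, which is the structural test this architecture must pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat
from .dual_vae import LatentSeriesBatch
from . import nn


@dataclass
class NoiseBatch:
    """Paired i.i.d. U(0,1) noise streams, N x T x noise_dim each."""

    upsilon_cont: np.ndarray
    upsilon_disc: np.ndarray

    def __post_init__(self):
        for a in (self.upsilon_cont, self.upsilon_disc):
            if a.min() < 0.0 or a.max() > 1.0:
                raise ValueError("noise entries must lie in [0, 1]")
        if self.upsilon_cont.shape != self.upsilon_disc.shape:
            raise ValueError("paired noise streams must share shape")


def sample_noise(n: int, T: int, noise_dim: int, seed: int = 0,
                 per_timestep: bool = True) -> NoiseBatch:
    """Seeded uniform noise; ``per_timestep=False`` holds one draw fixed
    across the sequence."""
    if min(n, T, noise_dim) < 0 or T == 0 or noise_dim == 0:
        raise ValueError("dims must be positive")
    rng = np.random.default_rng(seed)
    if per_timestep:
        uc = rng.uniform(size=(n, T, noise_dim))
        ud = rng.uniform(size=(n, T, noise_dim))
    else:
        uc = np.repeat(rng.uniform(size=(n, 1, noise_dim)), T, axis=1)
        ud = np.repeat(rng.uniform(size=(n, 1, noise_dim)), T, axis=1)
    return NoiseBatch(upsilon_cont=uc, upsilon_disc=ud)


class BLSTMParams:
    """Weights of the two coupled streams plus output projections.

    Per domain d and the fused gate block (i, f, o, c~): input weights W_x,
    own-stream recurrent weights W_h, cross-stream recurrent weights W_hx,
    bias b; plus the per-domain latent projection f_conn.
    """

    def __init__(self, rng: np.random.Generator, noise_dim: int, hidden: int,
                 latent_dim: int, n_labels: int = 0):
        self.hidden = hidden
        self.noise_dim = noise_dim
        self.latent_dim = latent_dim
        self.n_labels = n_labels
        n_in = noise_dim + n_labels
        self.Wx, self.Wh, self.Wcross, self.b, self.f_conn = {}, {}, {}, {}, {}
        for d in ("C", "D"):
            self.Wx[d] = Tensor(nn.glorot(rng, n_in, 4 * hidden), requires_grad=True)
            self.Wh[d] = Tensor(nn.glorot(rng, hidden, 4 * hidden), requires_grad=True)
            self.Wcross[d] = Tensor(nn.glorot(rng, hidden, 4 * hidden),
                                    requires_grad=True)
            self.b[d] = Tensor(np.zeros(4 * hidden), requires_grad=True)
            self.f_conn[d] = nn.Linear(rng, hidden, latent_dim)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for d in ("C", "D"):
            ps += [self.Wx[d], self.Wh[d], self.Wcross[d], self.b[d]]
            ps += self.f_conn[d].parameters()
        return ps

    def zero_cross_weights(self) -> None:
        """Pin the cross-stream connections to zero (uncoupled ablations)."""
        for d in ("C", "D"):
            self.Wcross[d].data[...] = 0.0


@dataclass
class BLSTMState:
    h_cont: Tensor
    c_cont: Tensor
    h_disc: Tensor
    c_disc: Tensor

    @staticmethod
    def zeros(n: int, hidden: int) -> "BLSTMState":
        z = lambda: Tensor(np.zeros((n, hidden)))
        return BLSTMState(z(), z(), z(), z())


def _gates(z: Tensor, H: int) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    return (z[:, 0 * H:1 * H].sigmoid(), z[:, 1 * H:2 * H].sigmoid(),
            z[:, 2 * H:3 * H].sigmoid(), z[:, 3 * H:4 * H].tanh())


def blstm_step(state: BLSTMState, u_cont: Tensor, u_disc: Tensor,
               params: BLSTMParams) -> BLSTMState:
    """One coupled transition for both streams.

    Each stream's fused pre-activation is
    W_x u_t^d + W_cross h_{t-1}^{d'} + W_own h_{t-1}^d + b, then the usual
    LSTM gating c = f*c + i*c~, h = o*tanh(c).
    """
    H = params.hidden
    prev = {"C": (state.h_cont, state.c_cont), "D": (state.h_disc, state.c_disc)}
    inputs = {"C": u_cont, "D": u_disc}
    new = {}
    for d, d_other in (("C", "D"), ("D", "C")):
        h_own, c_own = prev[d]
        h_cross = prev[d_other][0]
        z = inputs[d] @ params.Wx[d] + h_cross @ params.Wcross[d] \
            + h_own @ params.Wh[d] + params.b[d]
        i, f, o, g = _gates(z, H)
        c = f * c_own + i * g
        h = o * c.tanh()
        if not np.isfinite(h.data).all():
            raise FloatingPointError("non-finite BLSTM state")
        new[d] = (h, c)
    return BLSTMState(new["C"][0], new["C"][1], new["D"][0], new["D"][1])


def generate_latents(noise: NoiseBatch, params: BLSTMParams,
                     labels: Optional[np.ndarray] = None,
                     as_tensors: bool = False):
    """Unroll the CRN from zero state; per-domain projections emit the
    paired synthetic latent trajectories.  Conditional mode concatenates the
    one-hot label to the noise at every timestep."""
    n, T, _ = noise.upsilon_cont.shape
    if params.n_labels:
        if labels is None:
            raise ValueError("conditional generator requires labels")
        lab = Tensor(labels)
    state = BLSTMState.zeros(n, params.hidden)
    zc, zd = [], []
    for t in range(T):
        uc = Tensor(noise.upsilon_cont[:, t, :])
        ud = Tensor(noise.upsilon_disc[:, t, :])
        if params.n_labels:
            uc = concat([uc, lab], axis=-1)
            ud = concat([ud, lab], axis=-1)
        state = blstm_step(state, uc, ud, params)
        zc.append(params.f_conn["C"](state.h_cont))
        zd.append(params.f_conn["D"](state.h_disc))
    from .autodiff import stack
    zc_t, zd_t = stack(zc, axis=1), stack(zd, axis=1)
    if as_tensors:
        return zc_t, zd_t
    return LatentSeriesBatch(z_cont=zc_t.data, z_disc=zd_t.data)
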