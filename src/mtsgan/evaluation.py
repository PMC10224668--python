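"""Fidelity and correlation battery for mixed-type sequence synthesis.

Implements the full evaluation protocol: kernel two-sample MMD on the
continuous channels, dimension-wise Bernoulli probabilities on the discrete
channels, a post-hoc bidirectional-LSTM discriminative score, per-timepoint
trajectory summaries, pairwise-correlation heatmaps with the CorAcc /
mu_abs agreement statistics, and autocorrelation-function comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .autodiff import Tensor
from .data import MixedSeriesBatch
from . import nn


# ---------------------------------------------------------------------------
# maximum mean discrepancy
# ---------------------------------------------------------------------------

@dataclass
class KernelConfig:
    """Summed-Gaussian kernel: K(x,x') = sum_i exp(-||x-x'||_F^2 / sigma_i^2).

    Bandwidths default to the median heuristic (median pairwise Frobenius
    distance over the pooled sample) scaled by the listed multipliers.
    """

    bandwidths: Optional[list[float]] = None
    median_multipliers: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)

    def resolve(self, sq_dists: np.ndarray) -> np.ndarray:
        if self.bandwidths is not None:
            sig = np.asarray(self.bandwidths, dtype=float)
        else:
            med = np.sqrt(np.median(sq_dists[sq_dists > 0])) \
                if (sq_dists > 0).any() else 1.0
            sig = med * np.asarray(self.median_multipliers)
        if (sig <= 0).any():
            raise ValueError("bandwidths must be positive")
        return sig


def _flatten(x: np.ndarray) -> np.ndarray:
    return x.reshape(x.shape[0], -1)


def mmd(real: np.ndarray, synth: np.ndarray,
        kernel: Optional[KernelConfig] = None) -> float:
    """Unbiased squared MMD between two sets of T x |J| matrices.

    The Frobenius norm of the matrix difference equals the Euclidean norm of
    the flattened sequences, so distances are computed on N x (T|J|) rows.
    """
    kernel = kernel or KernelConfig()
    n, m = real.shape[0], synth.shape[0]
    if n < 2 or m < 2:
        raise ValueError("unbiased MMD needs at least 2 records per side")
    if real.shape[1:] != synth.shape[1:]:
        raise ValueError("real and synthetic must share T and |J|")
    xr, xs = _flatten(real), _flatten(synth)
    dxx = cdist(xr, xr, "sqeuclidean")
    dyy = cdist(xs, xs, "sqeuclidean")
    dxy = cdist(xr, xs, "sqeuclidean")
    pooled = np.concatenate([dxx[np.triu_indices(n, 1)],
                             dyy[np.triu_indices(m, 1)], dxy.ravel()])
    sigmas = kernel.resolve(pooled)

    def ksum(d: np.ndarray) -> np.ndarray:
        return sum(np.exp(-d / s ** 2) for s in sigmas)

    kxx, kyy, kxy = ksum(dxx), ksum(dyy), ksum(dxy)
    term_xx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    term_yy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    term_xy = 2.0 * kxy.mean()
    return float(term_xx + term_yy - term_xy)


# ---------------------------------------------------------------------------
# dimension-wise probability
# ---------------------------------------------------------------------------

@dataclass
class DimensionWiseResult:
    p_real: np.ndarray       # |K| x T activation rates
    p_synth: np.ndarray
    rmse: float
    cc: Optional[float]      # Pearson r across all (k, t) pairs; None if undefined


def dimension_wise_probability(real: np.ndarray,
                               synth: np.ndarray) -> DimensionWiseResult:
    """Per-(channel, timestamp) Bernoulli rates compared by RMSE and Pearson r."""
    if real.shape[1:] != synth.shape[1:]:
        raise ValueError("discrete tensors must share T and |K|")
    p_r = real.mean(axis=0).T       # |K| x T
    p_s = synth.mean(axis=0).T
    diff = p_r - p_s
    rmse = float(np.sqrt((diff ** 2).mean()))
    cc: Optional[float]
    if p_r.std() < 1e-12 or p_s.std() < 1e-12:
        warnings.warn("constant probability vector: correlation undefined")
        cc = None
    else:
        cc = float(np.corrcoef(p_r.ravel(), p_s.ravel())[0, 1])
    return DimensionWiseResult(p_real=p_r, p_synth=p_s, rmse=rmse, cc=cc)


# ---------------------------------------------------------------------------
# discriminative score
# ---------------------------------------------------------------------------

def _stack_channels(batch: MixedSeriesBatch) -> np.ndarray:
    return np.concatenate([batch.x_cont, batch.x_disc], axis=2)


def discriminative_score(real: MixedSeriesBatch, synth: MixedSeriesBatch,
                         hidden: int = 32, epochs: int = 50, lr: float = 1e-3,
                         batch_size: int = 128, seed: int = 0,
                         n_seeds: int = 1) -> tuple[float, float]:
    """Held-out accuracy of a freshly initialized Bi-LSTM real-vs-synthetic
    critic; 0.5 means indistinguishable.

    Returns (mean accuracy, standard error) over ``n_seeds`` training runs.
    """
    if real.n != synth.n:
        raise ValueError("real and synthetic sets must have equal size")
    if min(real.n, synth.n) < 20:
        raise ValueError("need at least 20 records per side")
    x = np.concatenate([_stack_channels(real), _stack_channels(synth)], axis=0)
    y = np.concatenate([np.ones(real.n), np.zeros(synth.n)])

    accs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        idx_tr, idx_te = train_test_split(
            np.arange(len(y)), test_size=0.2, stratify=y,
            random_state=int(rng.integers(2 ** 31)))
        critic = nn.BiLSTMClassifier(rng, x.shape[2], hidden, 1)
        opt = nn.Adam(critic.parameters(), lr=lr)
        for _ in range(epochs):
            for mb in nn.minibatches(len(idx_tr), batch_size, rng):
                rows = idx_tr[mb]
                logits = critic.logits(Tensor(x[rows]))[:, 0]
                loss = nn.bce_with_logits(logits, y[rows]).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        pred = critic.logits(Tensor(x[idx_te])).data[:, 0] > 0
        accs.append(float((pred == (y[idx_te] > 0.5)).mean()))
    accs = np.asarray(accs)
    se = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return float(accs.mean()), se


# ---------------------------------------------------------------------------
# trajectory summaries
# ---------------------------------------------------------------------------

def trajectory_summary(batch: MixedSeriesBatch) -> dict:
    """Per-feature per-timepoint mean/SD (continuous) and rates (discrete)."""
    out = {
        "cont_mean": batch.x_cont.mean(axis=0),   # T x |J|
        "disc_rate": batch.x_disc.mean(axis=0),   # T x |K|
        "sd_defined": batch.n > 1,
    }
    if batch.n > 1:
        out["cont_sd"] = batch.x_cont.std(axis=0, ddof=1)
    else:
        out["cont_sd"] = np.full_like(out["cont_mean"], np.nan)
    return out


def plot_trajectories(real: MixedSeriesBatch, synth: MixedSeriesBatch, path) -> None:
    """Mean +/- 1 SD overlays of real vs synthetic, one panel per feature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sr, ss = trajectory_summary(real), trajectory_summary(synth)
    nj, nk = real.dim_cont, real.dim_disc
    fig, axes = plt.subplots(1, nj + nk, figsize=(3 * (nj + nk), 3),
                             squeeze=False)
    t = np.arange(real.T)
    for j in range(nj):
        ax = axes[0][j]
        for s, lbl, c in ((sr, "real", "C0"), (ss, "synthetic", "C1")):
            m, sd = s["cont_mean"][:, j], s["cont_sd"][:, j]
            ax.plot(t, m, color=c, label=lbl)
            ax.fill_between(t, m - sd, m + sd, color=c, alpha=0.2)
        ax.set_title(real.feature_names_cont[j])
    for k in range(nk):
        ax = axes[0][nj + k]
        ax.plot(t, sr["disc_rate"][:, k], "C0", label="real")
        ax.plot(t, ss["disc_rate"][:, k], "C1", label="synthetic")
        ax.set_title(real.feature_names_disc[k])
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pairwise correlations + CorAcc / mu_abs
# ---------------------------------------------------------------------------

def ppc_heatmap(batch: MixedSeriesBatch, stride_hours: int = 3
                ) -> tuple[np.ndarray, list[str]]:
    """Pearson correlations between (feature, sampled-timestamp) columns.

    Timestamps are subsampled every ``stride_hours`` bins; continuous and
    discrete channels both enter as numeric columns.  Zero-variance columns
    get zero correlation rows (flagged by a warning).
    """
    ts = np.arange(0, batch.T, stride_hours)
    cols, names = [], []
    for j, name in enumerate(batch.feature_names_cont):
        for t in ts:
            cols.append(batch.x_cont[:, t, j])
            names.append(f"{name}@{t}h")
    for k, name in enumerate(batch.feature_names_disc):
        for t in ts:
            cols.append(batch.x_disc[:, t, k])
            names.append(f"{name}@{t}h")
    X = np.stack(cols, axis=1)
    sd = X.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance columns; "
                      "their correlations set to 0")
    Xs = (X - X.mean(axis=0)) / np.where(degenerate, 1.0, sd)
    corr = (Xs.T @ Xs) / X.shape[0]
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr, names


# correlation strength levels (seven intervals; upper bin closed at 1)
CORR_BINS = (-1.0, -0.5, -0.3, -0.1, 0.1, 0.3, 0.5, 1.0)


def _bin_assign(a: np.ndarray) -> np.ndarray:
    # [-1,-0.5), [-0.5,-0.3), [-0.3,-0.1), [-0.1,0.1), [0.1,0.3), [0.3,0.5), [0.5,1]
    idx = np.digitize(a, CORR_BINS[1:-1], right=False)
    return idx


def coracc_mu_abs(real_heatmap: np.ndarray,
                  synth_heatmap: np.ndarray) -> tuple[float, float]:
    """CorAcc = fraction of off-diagonal pairs in the same correlation bin;
    mu_abs = mean absolute off-diagonal difference."""
    A, B = np.asarray(real_heatmap), np.asarray(synth_heatmap)
    if A.shape != B.shape:
        raise ValueError("heatmaps must share shape")
    off = ~np.eye(A.shape[0], dtype=bool)
    mu_abs = float(np.abs(A - B)[off].mean())
    coracc = float((_bin_assign(A[off]) == _bin_assign(B[off])).mean())
    return coracc, mu_abs


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def _sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-series sample ACF; x is N x T, returns N x (max_lag+1).

    Constant series yield NaN rows (handled by the caller)."""
    xc = x - x.mean(axis=1, keepdims=True)
    denom = (xc ** 2).sum(axis=1)
    out = np.empty((x.shape[0], max_lag + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        for h in range(max_lag + 1):
            num = (xc[:, : x.shape[1] - h] * xc[:, h:]).sum(axis=1)
            out[:, h] = num / denom
    return out


@dataclass
class ACFResult:
    lags: np.ndarray
    acf_real: np.ndarray           # F x (max_lag+1) patient-averaged curves
    acf_synth: np.ndarray
    rmse: np.ndarray               # per feature
    n_excluded_real: int
    n_excluded_synth: int
    feature_names: list[str]


def acf_compare(real: MixedSeriesBatch, synth: MixedSeriesBatch,
                max_lag: int = 23) -> ACFResult:
    """Patient-averaged ACF curves per feature, plus real-vs-synthetic RMSE.

    ACFs are computed per patient then averaged so every patient contributes
    equally; constant series are excluded (count reported)."""
    if max_lag >= real.T:
        raise ValueError("max_lag must be < T")
    names = real.feature_names_cont + real.feature_names_disc

    def curves(batch: MixedSeriesBatch) -> tuple[np.ndarray, int]:
        allx = np.concatenate([batch.x_cont, batch.x_disc], axis=2)
        out = np.empty((allx.shape[2], max_lag + 1))
        excluded = 0
        for f in range(allx.shape[2]):
            acfs = _sample_acf(allx[:, :, f], max_lag)
            ok = np.isfinite(acfs).all(axis=1)
            excluded += int((~ok).sum())
            out[f] = acfs[ok].mean(axis=0) if ok.any() else np.nan
        return out, excluded

    ar, er = curves(real)
    asn, es = curves(synth)
    rmse = np.sqrt(np.nanmean((ar - asn) ** 2, axis=1))
    return ACFResult(lags=np.arange(max_lag + 1), acf_real=ar, acf_synth=asn,
                     rmse=rmse, n_excluded_real=er, n_excluded_synth=es,
                     feature_names=names)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    mmd: float
    dwp_rmse: float
    dwp_cc: Optional[float]
    disc_score: float
    disc_score_se: float
    coracc: float
    mu_abs: float
    acf_rmse: dict[str, float]
    trajectories_real: dict = field(repr=False, default_factory=dict)
    trajectories_synth: dict = field(repr=False, default_factory=dict)

    def validate(self) -> None:
        # the unbiased estimator may dip below zero by O(1/n) under the null
        assert self.mmd >= -0.1, "MMD below numerics tolerance"
        assert self.dwp_rmse >= 0
        assert 0.0 <= self.disc_score <= 1.0
        assert 0.0 <= self.coracc <= 1.0
        assert self.mu_abs >= 0
        assert all(v >= 0 or np.isnan(v) for v in self.acf_rmse.values())

    def to_dict(self) -> dict:
        return {
            "mmd": self.mmd, "dwp_rmse": self.dwp_rmse, "dwp_cc": self.dwp_cc,
            "disc_score": self.disc_score, "disc_score_se": self.disc_score_se,
            "coracc": self.coracc, "mu_abs": self.mu_abs,
            "acf_rmse": self.acf_rmse,
        }


def evaluate(real: MixedSeriesBatch, synth: MixedSeriesBatch,
             kernel: Optional[KernelConfig] = None, seed: int = 0,
             disc_epochs: int = 50, disc_seeds: int = 3,
             stride_hours: int = 3, max_lag: Optional[int] = None) -> EvalReport:
    """Run the full battery and return an :class:`EvalReport`."""
    max_lag = max_lag if max_lag is not None else real.T - 1
    m = mmd(real.x_cont, synth.x_cont, kernel)
    dwp = dimension_wise_probability(real.x_disc, synth.x_disc)
    n_eq = min(real.n, synth.n)
    ds, ds_se = discriminative_score(
        real.subset(np.arange(n_eq)), synth.subset(np.arange(n_eq)),
        epochs=disc_epochs, seed=seed, n_seeds=disc_seeds)
    hr, _ = ppc_heatmap(real, stride_hours)
    hs, _ = ppc_heatmap(synth, stride_hours)
    coracc, mu_abs = coracc_mu_abs(hr, hs)
    acf = acf_compare(real, synth, max_lag=max_lag)
    report = EvalReport(
        mmd=m, dwp_rmse=dwp.rmse, dwp_cc=dwp.cc, disc_score=ds,
        disc_score_se=ds_se, coracc=coracc, mu_abs=mu_abs,
        acf_rmse={n: float(v) for n, v in zip(acf.feature_names, acf.rmse)},
        trajectories_real=trajectory_summary(real),
        trajectories_synth=trajectory_summary(synth))
    report.validate()
    return report
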