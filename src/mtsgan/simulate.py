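"""Ground-truth generator of ICU-like mixed-type trajectories.

A shared stationary Gaussian AR(1) latent state drives both data types,
which is what makes the cross-type coupling real and analytically
checkable: physiology (continuous channels) is a linear read-out of the
latent state plus observation noise, and interventions (binary channels)
are Bernoulli draws whose log-odds are a linear read-out of the *same*
state.  Closed-form moments (stationary variance 1/(1-a^2), lag-h
autocorrelation a^h) serve as recovery oracles for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import ConditionVocabulary, DatasetManifest, MixedSeriesBatch


def _default_loading_cont(dim_cont: int, latent_dim: int) -> np.ndarray:
    """Deterministic non-degenerate loading pattern: each feature loads
    mostly on one latent dim, with a weak secondary loading."""
    L = np.zeros((dim_cont, latent_dim))
    for j in range(dim_cont):
        L[j, j % latent_dim] = 1.0
        L[j, (j + 1) % latent_dim] = 0.3
    return L


def _default_loading_disc(dim_disc: int, latent_dim: int) -> np.ndarray:
    L = np.zeros((dim_disc, latent_dim))
    for k in range(dim_disc):
        L[k, k % latent_dim] = 2.0
    return L


@dataclass
class SimulatorConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 24 hourly bins, 5 physiological channels, 2 intervention
    channels, a 2-dimensional latent health state with AR coefficient 0.8
    and observation noise SD 0.5 — small desk-scale dimensions with the
    same temporal-coupling structure as an hourly pre-endpoint ICU window.
    """

    n_patients: int = 1000
    T: int = 24
    dim_cont: int = 5
    dim_disc: int = 2
    latent_dim: int = 2
    ar_coef: float = 0.8
    noise_sd_cont: float = 0.5
    loading_cont: Optional[np.ndarray] = None
    loading_disc: Optional[np.ndarray] = None
    intercept_disc: Optional[np.ndarray] = None
    label_threshold: Optional[float] = 0.0   # on the mean latent trajectory
    seed: int = 0

    def __post_init__(self):
        if not (abs(self.ar_coef) < 1):
            raise ValueError("|ar_coef| must be < 1 for stationarity")
        if self.noise_sd_cont <= 0:
            raise ValueError("noise_sd_cont must be positive")
        if self.loading_cont is None:
            self.loading_cont = _default_loading_cont(self.dim_cont, self.latent_dim)
        if self.loading_disc is None:
            self.loading_disc = _default_loading_disc(self.dim_disc, self.latent_dim)
        if self.intercept_disc is None:
            self.intercept_disc = np.zeros(self.dim_disc)
        self.loading_cont = np.asarray(self.loading_cont, dtype=float)
        self.loading_disc = np.asarray(self.loading_disc, dtype=float)
        self.intercept_disc = np.asarray(self.intercept_disc, dtype=float)
        if self.loading_cont.shape != (self.dim_cont, self.latent_dim):
            raise ValueError("loading_cont must be |J| x latent_dim")
        if self.loading_disc.shape != (self.dim_disc, self.latent_dim):
            raise ValueError("loading_disc must be |K| x latent_dim")

    def feature_names(self) -> tuple[list[str], list[str]]:
        cont = [f"vital_{j}" for j in range(self.dim_cont)]
        disc = [f"d:intervention_{k}" for k in range(self.dim_disc)]
        return cont, disc


def _latent_paths(config: SimulatorConfig, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) paths, shape n x T x latent_dim."""
    a = config.ar_coef
    sd0 = 1.0 / np.sqrt(1.0 - a ** 2)     # stationary SD with unit innovations
    s = np.empty((n, config.T, config.latent_dim))
    s[:, 0] = rng.normal(0.0, sd0, size=(n, config.latent_dim))
    innov = rng.normal(0.0, 1.0, size=(n, config.T - 1, config.latent_dim))
    for t in range(1, config.T):
        s[:, t] = a * s[:, t - 1] + innov[:, t - 1]
    return s


def simulate_batch(config: SimulatorConfig) -> MixedSeriesBatch:
    """Draw a fully reproducible batch under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s = _latent_paths(config, config.n_patients, rng)

    x_cont = s @ config.loading_cont.T + rng.normal(
        0.0, config.noise_sd_cont,
        size=(config.n_patients, config.T, config.dim_cont))

    logits = s @ config.loading_disc.T + config.intercept_disc
    p = 1.0 / (1.0 + np.exp(-logits))
    x_disc = (rng.uniform(size=p.shape) < p).astype(float)

    labels = None
    if config.label_threshold is not None:
        # two outcome classes split on the patient's mean latent trajectory
        score = s.mean(axis=(1, 2))
        cls = (score > config.label_threshold).astype(int)
        labels = np.zeros((config.n_patients, 2))
        labels[np.arange(config.n_patients), cls] = 1.0

    cont_names, disc_names = config.feature_names()
    return MixedSeriesBatch(x_cont=x_cont, x_disc=x_disc, labels=labels,
                            feature_names_cont=cont_names,
                            feature_names_disc=disc_names)


def make_manifest(config: SimulatorConfig,
                  batch: Optional[MixedSeriesBatch] = None) -> DatasetManifest:
    vocab = None
    if batch is not None and batch.labels is not None:
        counts = batch.labels.sum(axis=0).astype(int).tolist()
        vocab = ConditionVocabulary(
            class_names=[f"class_{i}" for i in range(len(counts))], counts=counts)
    cont_names, disc_names = config.feature_names()
    return DatasetManifest(
        n_patients=config.n_patients, T=config.T, dim_cont=config.dim_cont,
        dim_disc=config.dim_disc, label_vocabulary=vocab,
        source="mtsgan simulator (shared AR(1) latent state)",
        feature_names_cont=cont_names, feature_names_disc=disc_names)


@dataclass
class TheoreticalMoments:
    mean_cont: np.ndarray          # |J|
    var_cont: np.ndarray           # |J|
    acf_cont: np.ndarray           # |J| x (max_lag+1), ACF of the observed series
    acf_signal: np.ndarray         # |J| x (max_lag+1), noise-free signal part
    rate_disc: np.ndarray          # |K|, MC-estimated stationary activation rate


def theoretical_moments(config: SimulatorConfig, max_lag: int = 23,
                        mc_draws: int = 100_000,
                        mc_seed: int = 12345) -> TheoreticalMoments:
    """Closed-form continuous-channel moments and MC discrete rates.

    Latent dims are independent AR(1) with stationary variance
    v = 1/(1-a^2) and autocovariance v * a^h.  A continuous feature with
    loading row ``l`` has signal variance ``v * ||l||^2``; observation noise
    adds ``noise_sd^2`` at lag 0 only, so the observed ACF is the signal ACF
    a^h shrunk by the signal-to-total-variance ratio at h >= 1.
    """
    a = config.ar_coef
    v = 1.0 / (1.0 - a ** 2)
    L = config.loading_cont
    sig_var = v * (L ** 2).sum(axis=1)
    tot_var = sig_var + config.noise_sd_cont ** 2
    lags = np.arange(max_lag + 1)
    acf_signal = np.tile(a ** lags, (config.dim_cont, 1))
    shrink = (sig_var / tot_var)[:, None]
    acf_obs = acf_signal * shrink
    acf_obs[:, 0] = 1.0

    rng = np.random.default_rng(mc_seed)
    s = rng.normal(0.0, np.sqrt(v), size=(mc_draws, config.latent_dim))
    logits = s @ config.loading_disc.T + config.intercept_disc
    rate = (1.0 / (1.0 + np.exp(-logits))).mean(axis=0)

    return TheoreticalMoments(
        mean_cont=np.zeros(config.dim_cont), var_cont=tot_var,
        acf_cont=acf_obs, acf_signal=acf_signal, rate_disc=rate)
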