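"""Utility harness: intervention-status prediction under TRTR/TSTR/TSRTR.

The task: observe the first 12 h of the continuous channels and predict the
status trajectory of one binary intervention channel over the next 12 h,
collapsed into four outcome classes.  The class is anchored at the first
prediction-window timestep: an intervention that begins on either stays on
throughout (*Stay on*) or goes off at some point (*Switch off*); one that
begins off either comes on at some point (*Onset*) or stays off
(*Stay off*).  These four classes exhaustively partition every possible
binary prediction window.

Training regimes: TRTR trains on the real utility sub-train set A'_Tr;
TSTR trains on the synthetic set B; TSRTR-alpha augments A'_Tr with an
alpha fraction of B; TSRTR-beta augments B with a beta fraction of A'_Tr.
All regimes test on the held-out real sub-test set A'_Te.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor
from .data import MixedSeriesBatch, SplitPlan
from . import nn

OUTCOME_CLASSES = ("Stay on", "Onset", "Switch off", "Stay off")
SCENARIOS = ("TRTR", "TSTR", "TSRTR_alpha", "TSRTR_beta")


@dataclass
class InterventionWindowing:
    """12 h observation followed by 12 h prediction on a 24 h grid."""

    observation: range = range(0, 12)
    prediction: range = range(12, 24)

    def __post_init__(self):
        total = list(self.observation) + list(self.prediction)
        if sorted(total) != list(range(len(total))):
            raise ValueError("windows must partition the time axis")


@dataclass
class AugmentationScenario:
    mode: str
    ratio: Optional[float] = None

    def __post_init__(self):
        if self.mode not in SCENARIOS:
            raise ValueError(f"mode must be one of {SCENARIOS}")
        needs_ratio = self.mode.startswith("TSRTR")
        if needs_ratio and (self.ratio is None or not (0 < self.ratio <= 1)):
            raise ValueError("TSRTR modes require ratio in (0, 1]")
        if not needs_ratio and self.ratio is not None:
            raise ValueError("ratio only applies to TSRTR modes")


def label_outcomes(batch: MixedSeriesBatch, intervention_channel: str,
                   windowing: Optional[InterventionWindowing] = None
                   ) -> np.ndarray:
    """One outcome class index per patient (see OUTCOME_CLASSES)."""
    windowing = windowing or InterventionWindowing()
    if intervention_channel not in batch.feature_names_disc:
        raise ValueError(f"unknown intervention channel {intervention_channel!r}")
    k = batch.feature_names_disc.index(intervention_channel)
    pred = batch.x_disc[:, list(windowing.prediction), k]
    return classify_windows(pred)


def classify_windows(pred: np.ndarray) -> np.ndarray:
    """Classify binary prediction windows (N x W) into the four outcomes."""
    begins_on = pred[:, 0] == 1
    all_on = pred.min(axis=1) == 1
    all_off = pred.max(axis=1) == 0
    out = np.empty(pred.shape[0], dtype=int)
    out[begins_on & all_on] = 0                    # Stay on
    out[~begins_on & ~all_off] = 1                 # Onset
    out[begins_on & ~all_on] = 2                   # Switch off
    out[~begins_on & all_off] = 3                  # Stay off
    return out


def build_scenario(plan: SplitPlan, scenario: AugmentationScenario,
                   seed: int = 0) -> tuple[list, np.ndarray]:
    """Training multiset and test indices for one regime.

    Returns (train_items, test_indices): train items are ``("real", i)`` or
    ``("synth", i)`` tags so synthetic records are never confused with real
    indices; the test set is always A'_Te.
    """
    rng = np.random.default_rng(seed)
    if scenario.mode != "TRTR" and plan.synthetic is None:
        raise ValueError("synthetic set B not materialized")
    real_items = [("real", int(i)) for i in plan.subtrain]
    if scenario.mode == "TRTR":
        train = real_items
    else:
        n_b = plan.synthetic.n
        synth_items = [("synth", i) for i in range(n_b)]
        if scenario.mode == "TSTR":
            train = synth_items
        elif scenario.mode == "TSRTR_alpha":
            k = int(round(scenario.ratio * n_b))
            pick = rng.choice(n_b, size=k, replace=False)
            train = real_items + [("synth", int(i)) for i in pick]
        else:  # TSRTR_beta
            k = int(round(scenario.ratio * len(real_items)))
            pick = rng.choice(len(real_items), size=k, replace=False)
            train = synth_items + [real_items[i] for i in pick]
    return train, plan.subtest


def _gather(items: list, real: MixedSeriesBatch,
            synth: Optional[MixedSeriesBatch]) -> MixedSeriesBatch:
    real_idx = [i for kind, i in items if kind == "real"]
    synth_idx = [i for kind, i in items if kind == "synth"]
    parts = []
    if real_idx:
        parts.append(real.subset(np.asarray(real_idx)))
    if synth_idx:
        parts.append(synth.subset(np.asarray(synth_idx)))
    x_cont = np.concatenate([p.x_cont for p in parts], axis=0)
    x_disc = np.concatenate([p.x_disc for p in parts], axis=0)
    return MixedSeriesBatch(x_cont=x_cont, x_disc=x_disc,
                            feature_names_cont=real.feature_names_cont,
                            feature_names_disc=real.feature_names_disc)


def train_predictor(x_obs: np.ndarray, labels: np.ndarray, hidden: int = 64,
                    epochs: int = 50, lr: float = 1e-3, batch_size: int = 128,
                    seed: int = 0) -> nn.LSTMClassifier:
    """Recurrent 4-class classifier on the observation-window continuous
    channels (N x 12 x |J|)."""
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("single-class training data")
    rng = np.random.default_rng(seed)
    clf = nn.LSTMClassifier(rng, x_obs.shape[2], hidden, len(OUTCOME_CLASSES))
    onehot = np.eye(len(OUTCOME_CLASSES))[labels]
    opt = nn.Adam(clf.parameters(), lr=lr)
    for _ in range(epochs):
        for mb in nn.minibatches(len(labels), batch_size, rng):
            loss = nn.softmax_cross_entropy(clf.logits(Tensor(x_obs[mb])),
                                            onehot[mb])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return clf


def predict_proba(clf: nn.LSTMClassifier, x_obs: np.ndarray) -> np.ndarray:
    logits = clf.logits(Tensor(x_obs)).data
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def macro_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-rest AUROC averaged over classes present in the test labels."""
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("single-class test labels")
    absent = set(range(scores.shape[1])) - set(present.tolist())
    if absent:
        import warnings
        warnings.warn(f"classes {sorted(absent)} absent from test labels; excluded")
    aucs = []
    for c in present:
        aucs.append(roc_auc_score((labels == c).astype(int), scores[:, c]))
    return float(np.mean(aucs))


def run_utility_suite(real: MixedSeriesBatch, plan: SplitPlan,
                      intervention_channel: str,
                      scenarios: Sequence[AugmentationScenario],
                      repeats: int = 3, seed: int = 0,
                      predictor_kwargs: Optional[dict] = None,
                      skip_degenerate: bool = False) -> list[dict]:
    """Per-scenario mean +/- SD macro-AUROC with unpaired t-tests vs TRTR.

    Synthetic records carry their own outcome labels (label_outcomes applied
    to the generated intervention channel), which is what train-on-synthetic
    regimes require.  With ``skip_degenerate`` a scenario whose training
    labels collapse to a single class (e.g. a degenerate generator) yields a
    row with an ``error`` field instead of aborting the whole suite.
    """
    predictor_kwargs = predictor_kwargs or {}
    windowing = InterventionWindowing()
    obs = list(windowing.observation)
    lab_real = label_outcomes(real, intervention_channel, windowing)
    lab_synth = None
    if plan.synthetic is not None:
        lab_synth = label_outcomes(plan.synthetic, intervention_channel, windowing)

    def labels_for(items: list) -> np.ndarray:
        out = []
        for kind, i in items:
            out.append(lab_real[i] if kind == "real" else lab_synth[i])
        return np.asarray(out)

    results = []
    per_scenario_aucs: dict[str, list[float]] = {}
    for sc in scenarios:
        aucs = []
        failure = None
        for r in range(repeats):
            train_items, test_idx = build_scenario(plan, sc, seed=seed + r)
            assert not any(kind == "real" and i in set(test_idx.tolist())
                           for kind, i in train_items), "test leakage"
            tr_batch = _gather(train_items, real, plan.synthetic)
            y_tr = labels_for(train_items)
            try:
                clf = train_predictor(tr_batch.x_cont[:, obs, :], y_tr,
                                      seed=seed + r, **predictor_kwargs)
            except ValueError as e:
                if not skip_degenerate:
                    raise
                failure = str(e)
                break
            scores = predict_proba(clf, real.x_cont[test_idx][:, obs, :])
            aucs.append(macro_auroc(scores, lab_real[test_idx]))
        if failure is not None:
            results.append({"scenario": sc.mode, "ratio": sc.ratio,
                            "channel": intervention_channel,
                            "auroc_mean": None, "auroc_sd": None,
                            "n_repeats": 0, "error": failure})
            continue
        key = sc.mode if sc.ratio is None else f"{sc.mode}@{sc.ratio}"
        per_scenario_aucs[key] = aucs
        results.append({"scenario": sc.mode, "ratio": sc.ratio,
                        "channel": intervention_channel,
                        "auroc_mean": float(np.mean(aucs)),
                        "auroc_sd": float(np.std(aucs, ddof=1)) if repeats > 1 else 0.0,
                        "n_repeats": repeats})
    trtr = per_scenario_aucs.get("TRTR")
    if trtr is not None and repeats > 1:
        for row in results:
            if "error" in row:
                continue
            key = row["scenario"] if row["ratio"] is None \
                else f"{row['scenario']}@{row['ratio']}"
            if key == "TRTR":
                row["p_vs_trtr"] = None
                continue
            t, p = stats.ttest_ind(per_scenario_aucs[key], trtr)
            row["p_vs_trtr"] = float(p)
    return results
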