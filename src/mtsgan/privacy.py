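"""Black-box membership inference against the generator.

The attacker holds the full candidate record set P, observes only a
synthetic sample S, and must decide which candidates were in the
generator's training data.  The decision rule is the standard
nearest-synthetic-distance attack: each candidate's distance to its nearest
synthetic record (standardized Euclidean on the flattened continuous
channels plus Hamming on the discrete channels, weighted sum) is computed,
and the attacker claims "member" for the lowest-distance fraction of
candidates equal to the true member fraction (quantile calibration).  A
generator that memorizes its training records is caught with accuracy and
recall near 1; one whose output is independent of membership pushes the
attack to coin-flipping (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import MixedSeriesBatch


@dataclass
class AttackSetup:
    candidates: MixedSeriesBatch      # the full record set P
    member_mask: np.ndarray           # true membership flags over P
    synthetic: MixedSeriesBatch       # observed synthetic sample S
    weight_cont: float = 1.0
    weight_disc: float = 1.0

    def __post_init__(self):
        self.member_mask = np.asarray(self.member_mask, dtype=bool)
        if len(self.member_mask) != self.candidates.n:
            raise ValueError("member mask must cover all candidates")
        if self.synthetic.n == 0:
            raise ValueError("empty synthetic sample")


@dataclass
class AttackResult:
    accuracy: float
    recall: float
    min_distances: np.ndarray
    claimed: np.ndarray


def _distances(setup: AttackSetup) -> np.ndarray:
    """Min over synthetic records of the weighted mixed-type distance."""
    pc = setup.candidates.x_cont.reshape(setup.candidates.n, -1)
    sc = setup.synthetic.x_cont.reshape(setup.synthetic.n, -1)
    sd = pc.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    d_cont = cdist(pc / sd, sc / sd, "euclidean")
    pd_ = setup.candidates.x_disc.reshape(setup.candidates.n, -1)
    sd_ = setup.synthetic.x_disc.reshape(setup.synthetic.n, -1)
    d_disc = cdist(pd_, sd_, "hamming") * pd_.shape[1]
    total = setup.weight_cont * d_cont + setup.weight_disc * d_disc
    return total.min(axis=1)


def membership_attack(setup: AttackSetup) -> AttackResult:
    """Quantile-calibrated nearest-distance attack; ties broken by index."""
    dist = _distances(setup)
    n_members = int(setup.member_mask.sum())
    order = np.lexsort((np.arange(len(dist)), dist))  # stable (distance, index)
    claimed = np.zeros(len(dist), dtype=bool)
    claimed[order[:n_members]] = True
    truth = setup.member_mask
    accuracy = float((claimed == truth).mean())
    recall = float(claimed[truth].mean()) if n_members else 0.0
    return AttackResult(accuracy=accuracy, recall=recall,
                        min_distances=dist, claimed=claimed)


def attack_vs_training_fraction(
        data: MixedSeriesBatch,
        train_and_generate: Callable[[MixedSeriesBatch, int, int], MixedSeriesBatch],
        fractions: Sequence[float] = (0.2, 0.5, 0.9),
        repeats: int = 3, seed: int = 0) -> list[dict]:
    """Attack success vs the fraction of P used to train the generator.

    ``train_and_generate(train_batch, n_synth, seed)`` is the pipeline
    closure: train the full model on the member subset, return a synthetic
    sample.  One row per (fraction, repeat); summary rows carry mean and SE.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        accs, recs = [], []
        for r in range(repeats):
            rep_seed = int(rng.integers(2 ** 31))
            mask = np.zeros(data.n, dtype=bool)
            n_mem = int(round(frac * data.n))
            members = np.random.default_rng(rep_seed).choice(
                data.n, size=n_mem, replace=False)
            mask[members] = True
            synth = train_and_generate(data.subset(members), data.n, rep_seed)
            res = membership_attack(AttackSetup(
                candidates=data, member_mask=mask, synthetic=synth))
            rows.append({"fraction": frac, "repeat": r,
                         "accuracy": res.accuracy, "recall": res.recall})
            accs.append(res.accuracy)
            recs.append(res.recall)
        rows.append({"fraction": frac, "repeat": "summary",
                     "accuracy": float(np.mean(accs)),
                     "accuracy_se": float(np.std(accs, ddof=1) / np.sqrt(repeats))
                     if repeats > 1 else 0.0,
                     "recall": float(np.mean(recs)),
                     "recall_se": float(np.std(recs, ddof=1) / np.sqrt(repeats))
                     if repeats > 1 else 0.0})
    return rows
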