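"""Typed containers and on-disk formats for mixed-type patient timeseries.

A record is one ICU stay binned onto a fixed hourly grid (time index 0 is
the earliest bin): ``|J|`` continuous physiological channels and ``|K|``
binary intervention channels, optionally a one-hot condition label per
patient.  Missing values are out of scope — inputs must arrive complete
(imputation belongs to the upstream extraction pipeline) and the readers
reject incomplete files rather than silently fill them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class ConditionVocabulary:
    """Names and per-class counts of the categorical condition labels."""

    class_names: list[str]
    counts: list[int]

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("condition class names must be unique")
        if len(self.counts) != len(self.class_names):
            raise ValueError("counts and class_names must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")


@dataclass
class DatasetManifest:
    """Shape metadata plus (optionally) the per-feature scaling statistics.

    ``scale_mean``/``scale_std`` hold the z-scoring statistics of the
    continuous channels, computed on the generator-training portion only so
    generated output can be mapped back to original units without test-set
    leakage.
    """

    n_patients: int
    T: int
    dim_cont: int
    dim_disc: int
    label_vocabulary: Optional[ConditionVocabulary] = None
    source: str = ""
    scale_mean: Optional[list[float]] = None
    scale_std: Optional[list[float]] = None
    feature_names_cont: Optional[list[str]] = None
    feature_names_disc: Optional[list[str]] = None

    def __post_init__(self):
        if min(self.n_patients, self.dim_cont, self.dim_disc) < 0:
            raise ValueError("dimensions must be nonnegative")
        if self.T < 2:
            raise ValueError("need at least two timesteps")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("n_patients", "T", "dim_cont", "dim_disc", "source",
              "scale_mean", "scale_std", "feature_names_cont",
              "feature_names_disc")}
        if self.label_vocabulary is not None:
            d["label_vocabulary"] = {
                "class_names": self.label_vocabulary.class_names,
                "counts": self.label_vocabulary.counts}
        return json.dumps(d, indent=1)

    @staticmethod
    def from_json(text: str) -> "DatasetManifest":
        d = json.loads(text)
        vocab = d.pop("label_vocabulary", None)
        if vocab is not None:
            vocab = ConditionVocabulary(**vocab)
        return DatasetManifest(label_vocabulary=vocab, **d)


@dataclass
class MixedSeriesBatch:
    """N aligned mixed-type sequences.

    ``x_cont``: float array N x T x |J|; ``x_disc``: {0,1} array N x T x |K|;
    ``labels``: optional one-hot N x |L|.
    """

    x_cont: np.ndarray
    x_disc: np.ndarray
    feature_names_cont: list[str]
    feature_names_disc: list[str]
    labels: Optional[np.ndarray] = None
    time_axis: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x_cont = np.asarray(self.x_cont, dtype=np.float64)
        self.x_disc = np.asarray(self.x_disc, dtype=np.float64)
        if self.x_cont.ndim != 3 or self.x_disc.ndim != 3:
            raise ValueError("x_cont and x_disc must be N x T x F arrays")
        n, t, j = self.x_cont.shape
        n2, t2, k = self.x_disc.shape
        if (n, t) != (n2, t2):
            raise ValueError("continuous and discrete tensors disagree on N or T")
        if j != len(self.feature_names_cont) or k != len(self.feature_names_disc):
            raise ValueError("feature name lists do not match tensor dims")
        if not np.isfinite(self.x_cont).all():
            raise ValueError("continuous values must be finite (no missing data)")
        if not np.isin(self.x_disc, (0.0, 1.0)).all():
            raise ValueError("discrete values must be exactly 0 or 1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.float64)
            if self.labels.shape[0] != n:
                raise ValueError("labels row count must equal N")
        if self.time_axis is None:
            self.time_axis = np.arange(t)

    @property
    def n(self) -> int:
        return self.x_cont.shape[0]

    @property
    def T(self) -> int:
        return self.x_cont.shape[1]

    @property
    def dim_cont(self) -> int:
        return self.x_cont.shape[2]

    @property
    def dim_disc(self) -> int:
        return self.x_disc.shape[2]

    def subset(self, idx: np.ndarray) -> "MixedSeriesBatch":
        return replace(
            self, x_cont=self.x_cont[idx], x_disc=self.x_disc[idx],
            labels=None if self.labels is None else self.labels[idx],
            time_axis=self.time_axis)

    def label_ids(self) -> Optional[np.ndarray]:
        return None if self.labels is None else np.argmax(self.labels, axis=1)


@dataclass
class SplitPlan:
    """Index partition: generator-train A (70%), and the held-out 30%
    divided into equal utility sub-train A'_Tr and sub-test A'_Te halves."""

    train: np.ndarray        # A
    subtrain: np.ndarray     # A'_Tr
    subtest: np.ndarray      # A'_Te
    synthetic: Optional[MixedSeriesBatch] = None  # B, |B| = |A'_Tr|

    def __post_init__(self):
        parts = [set(self.train.tolist()), set(self.subtrain.tolist()),
                 set(self.subtest.tolist())]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split parts must be disjoint")
        if abs(len(self.subtrain) - len(self.subtest)) > 1:
            raise ValueError("utility halves must differ by at most one record")


# ---------------------------------------------------------------------------
# long-format CSV
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["patient_id", "time_index", "feature", "value"]


def write_long_csv(batch: MixedSeriesBatch, path) -> None:
    """Serialize a batch to long format with deterministic row order.

    Rows are ordered by (patient, time, continuous features in name order,
    then discrete features in name order); floats keep round-trip precision.
    """
    cont_order = np.argsort(batch.feature_names_cont, kind="stable")
    disc_order = np.argsort(batch.feature_names_disc, kind="stable")
    rows = []
    for i in range(batch.n):
        for t in range(batch.T):
            for j in cont_order:
                rows.append((i, t, batch.feature_names_cont[j],
                             repr(float(batch.x_cont[i, t, j]))))
            for k in disc_order:
                rows.append((i, t, batch.feature_names_disc[k],
                             repr(float(batch.x_disc[i, t, k]))))
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    df.to_csv(path, index=False)


def read_long_csv(path, manifest: DatasetManifest) -> MixedSeriesBatch:
    """Assemble a dense batch from a long-format CSV.

    Every (patient, time, feature) cell must be present exactly once;
    discrete features must be exactly 0/1.  Patients are ordered by first
    appearance in the file.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "feature": str},
                     float_precision="round_trip")
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long CSV missing columns: {missing_cols}")

    # feature kind comes from the manifest when it carries names, otherwise
    # from the "d:" name-prefix convention the simulator emits
    names = list(df["feature"].unique())
    if manifest.feature_names_disc is not None:
        disc_set = set(manifest.feature_names_disc)
        cont_names = sorted(n for n in names if n not in disc_set)
        disc_names = sorted(n for n in names if n in disc_set)
    else:
        cont_names = sorted(n for n in names if not _is_discrete_name(n))
        disc_names = sorted(n for n in names if _is_discrete_name(n))
    if len(cont_names) != manifest.dim_cont or len(disc_names) != manifest.dim_disc:
        raise ValueError(
            f"manifest dims ({manifest.dim_cont},{manifest.dim_disc}) do not match "
            f"file features ({len(cont_names)} continuous, {len(disc_names)} discrete)")

    patients = list(dict.fromkeys(df["patient_id"]))  # first-appearance order
    p_idx = {p: i for i, p in enumerate(patients)}
    t_vals = df["time_index"].to_numpy()
    if t_vals.min() != 0:
        raise ValueError("time_index must be 0-based")
    T = int(t_vals.max()) + 1
    if T != manifest.T:
        raise ValueError(f"file has T={T}, manifest says T={manifest.T}")

    n = len(patients)
    x_cont = np.full((n, T, len(cont_names)), np.nan)
    x_disc = np.full((n, T, len(disc_names)), np.nan)
    c_idx = {f: j for j, f in enumerate(cont_names)}
    d_idx = {f: k for k, f in enumerate(disc_names)}

    pid = df["patient_id"].map(p_idx).to_numpy()
    feat = df["feature"].to_numpy()
    val = df["value"].to_numpy(dtype=np.float64)
    disc_set = set(disc_names)
    is_disc = np.array([f in disc_set for f in feat])
    fc = np.array([c_idx.get(f, -1) for f in feat])
    fd = np.array([d_idx.get(f, -1) for f in feat])
    seen_c = np.zeros(x_cont.shape, dtype=int)
    seen_d = np.zeros(x_disc.shape, dtype=int)
    x_cont[pid[~is_disc], t_vals[~is_disc], fc[~is_disc]] = val[~is_disc]
    x_disc[pid[is_disc], t_vals[is_disc], fd[is_disc]] = val[is_disc]
    np.add.at(seen_c, (pid[~is_disc], t_vals[~is_disc], fc[~is_disc]), 1)
    np.add.at(seen_d, (pid[is_disc], t_vals[is_disc], fd[is_disc]), 1)

    for arr_seen, arr_names in ((seen_c, cont_names), (seen_d, disc_names)):
        bad = np.argwhere(arr_seen != 1)
        if len(bad):
            i, t, f = bad[0]
            kind = "duplicate" if arr_seen[i, t, f] > 1 else "missing"
            raise ValueError(
                f"{kind} cell: patient={patients[i]}, time={t}, "
                f"feature={arr_names[f]}")

    bad_disc = np.argwhere(~np.isin(x_disc, (0.0, 1.0)))
    if len(bad_disc):
        i, t, k = bad_disc[0]
        raise ValueError(
            f"non-binary value in discrete feature: patient={patients[i]}, "
            f"time={t}, feature={disc_names[k]}, value={x_disc[i, t, k]}")

    return MixedSeriesBatch(x_cont=x_cont, x_disc=x_disc,
                            feature_names_cont=cont_names,
                            feature_names_disc=disc_names)


def _is_discrete_name(name: str) -> bool:
    return str(name).startswith("d:")


# ---------------------------------------------------------------------------
# dense archive (npz tensor container + JSON manifest sidecar)
# ---------------------------------------------------------------------------

def write_archive(batch: MixedSeriesBatch, path, manifest: DatasetManifest) -> None:
    path = Path(path)
    arrays = {"x_cont": batch.x_cont, "x_disc": batch.x_disc}
    if batch.labels is not None:
        arrays["labels"] = batch.labels
    np.savez_compressed(path, **arrays,
                        feature_names_cont=np.array(batch.feature_names_cont),
                        feature_names_disc=np.array(batch.feature_names_disc))
    sidecar = path.with_suffix(path.suffix + ".manifest.json") \
        if path.suffix != ".npz" else path.with_suffix(".manifest.json")
    sidecar.write_text(manifest.to_json())


def read_archive(path) -> tuple[MixedSeriesBatch, Optional[DatasetManifest]]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        batch = MixedSeriesBatch(
            x_cont=z["x_cont"], x_disc=z["x_disc"],
            labels=z["labels"] if "labels" in z else None,
            feature_names_cont=[str(s) for s in z["feature_names_cont"]],
            feature_names_disc=[str(s) for s in z["feature_names_disc"]])
    sidecar = path.with_suffix(".manifest.json")
    manifest = DatasetManifest.from_json(sidecar.read_text()) \
        if sidecar.exists() else None
    return batch, manifest


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(batch: MixedSeriesBatch,
                  fractions: dict[str, float] | None = None,
                  seed: int = 0) -> SplitPlan:
    """70/30 split into A and A', with A' halved into A'_Tr / A'_Te.

    Stratified by condition label when labels are present (per-class
    proportions preserved within one record).  With an odd held-out count
    the sub-test half receives the extra record.
    """
    fractions = fractions or {"train": 0.7, "test": 0.3}
    if abs(fractions["train"] + fractions["test"] - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if batch.n < 4:
        raise ValueError("need at least 4 records to split")
    rng = np.random.default_rng(seed)
    lab = batch.label_ids()

    groups: list[np.ndarray]
    if lab is None:
        groups = [rng.permutation(batch.n)]
    else:
        groups = [rng.permutation(np.flatnonzero(lab == c))
                  for c in np.unique(lab)]

    tr, s_tr, s_te = [], [], []
    n_sub_tr = n_sub_te = 0
    for g in groups:
        n_tr = int(round(fractions["train"] * len(g)))
        held = g[n_tr:]
        half = len(held) // 2
        tr.append(g[:n_tr])
        if len(held) % 2 == 1 and n_sub_te > n_sub_tr:
            # rebalance across strata so the global halves differ by <= 1;
            # on a global odd count A'_Te keeps the extra record
            s_tr.append(held[:half + 1])
            s_te.append(held[half + 1:])
        else:
            s_tr.append(held[:half])
            s_te.append(held[half:])
        n_sub_tr += len(s_tr[-1])
        n_sub_te += len(s_te[-1])
    plan = SplitPlan(train=np.sort(np.concatenate(tr)),
                     subtrain=np.sort(np.concatenate(s_tr)),
                     subtest=np.sort(np.concatenate(s_te)))
    if lab is not None:
        for part, name in ((plan.train, "A"), (plan.subtrain, "A'_Tr"),
                           (plan.subtest, "A'_Te")):
            present = set(lab[part].tolist())
            absent = set(np.unique(lab).tolist()) - present
            if absent:
                import warnings
                warnings.warn(f"label classes {sorted(absent)} absent from {name}")
    return plan


def standardize(batch: MixedSeriesBatch, manifest: DatasetManifest,
                fit_idx: np.ndarray) -> MixedSeriesBatch:
    """Z-score continuous channels using statistics of ``fit_idx`` rows only;
    stores the statistics in the manifest for later un-scaling."""
    mu = batch.x_cont[fit_idx].mean(axis=(0, 1))
    sd = batch.x_cont[fit_idx].std(axis=(0, 1))
    sd = np.where(sd < 1e-12, 1.0, sd)
    manifest.scale_mean = [float(v) for v in mu]
    manifest.scale_std = [float(v) for v in sd]
    return replace(batch, x_cont=(batch.x_cont - mu) / sd)


def unscale(x_cont: np.ndarray, manifest: DatasetManifest) -> np.ndarray:
    if manifest.scale_mean is None or manifest.scale_std is None:
        return x_cont
    return x_cont * np.asarray(manifest.scale_std) + np.asarray(manifest.scale_mean)
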