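"""Experiment configuration, provenance manifests, and checkpoint I/O."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_patients: int = 1000
    T: int = 24
    dim_cont: int = 5
    dim_disc: int = 2
    latent_dim: int = 2
    ar_coef: float = 0.8
    noise_sd_cont: float = 0.5


class DataSection(_Section):
    input_archive: Optional[str] = None   # use the simulator when absent
    train_fraction: float = 0.7


class DualVAESection(_Section):
    latent_dim: int = 4
    hidden: int = 64
    epochs: int = 50
    lr: float = 1e-3
    batch_size: int = 128
    beta_kl: float = 1.0
    beta0: float = 1.0
    beta1: float = 1.0
    beta2: float = 0.1
    beta3: float = 0.1
    tau: float = 0.5


class GeneratorSection(_Section):
    hidden: int = 64
    noise_dim: Optional[int] = None


class AdversarialSection(_Section):
    epochs: int = 100
    batch_size: int = 128
    lr_gen: float = 1e-3
    lr_disc: float = 1e-3
    ablation: str = "full"
    conditional: bool = False
    decoder_finetune: bool = False
    dp_clip_norm: Optional[float] = None
    dp_noise_multiplier: Optional[float] = None
    dp_delta: float = 1e-3
    dp_target_epsilon: Optional[float] = None


class EvaluationSection(_Section):
    enabled: bool = True
    disc_epochs: int = 50
    disc_seeds: int = 3
    stride_hours: int = 3


class DownstreamSection(_Section):
    enabled: bool = False
    channel: Optional[str] = None         # default: first discrete channel
    scenarios: list[str] = ["TRTR", "TSTR"]
    ratios: list[float] = [0.1, 0.25, 0.5]
    repeats: int = 3
    epochs: int = 50


class PrivacySection(_Section):
    enabled: bool = False
    fractions: list[float] = [0.2, 0.5, 0.9]
    repeats: int = 3


class ExperimentConfig(_Section):
    seed: int = 0
    output_dir: str = "mtsgan_run"
    data: DataSection = DataSection()
    simulate: SimulateSection = SimulateSection()
    dual_vae: DualVAESection = DualVAESection()
    generator: GeneratorSection = GeneratorSection()
    adversarial: AdversarialSection = AdversarialSection()
    evaluation: EvaluationSection = EvaluationSection()
    downstream: DownstreamSection = DownstreamSection()
    privacy: PrivacySection = PrivacySection()

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return ExperimentConfig.model_validate(raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive one stage's seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def version_manifest(config: Optional[ExperimentConfig] = None) -> dict:
    out = {"package": "mtsgan", "version": __version__}
    if config is not None:
        out["config_hash"] = config.config_hash()
        out["seed"] = config.seed
    return out


# ---------------------------------------------------------------------------
# checkpoints: a self-describing npz of the parameter arrays + meta JSON
# ---------------------------------------------------------------------------

def save_params(obj, path, meta: dict) -> None:
    """Persist any object exposing ``parameters()`` (ordered, deduped)."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(obj.parameters())}
    np.savez_compressed(path, **arrays)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_params_into(obj, path) -> None:
    """Restore arrays (in parameters() order) into a freshly built object."""
    with np.load(path) as z:
        params = obj.parameters()
        if len(z.files) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            p.data = z[f"param_{i}"]
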