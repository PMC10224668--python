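"""End-to-end orchestration: simulate/load -> pretrain -> adversarial
training -> generation -> evaluation (-> downstream utility -> membership
attack), with config-hash-stamped artifacts and checkpoint resume."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import adversarial, data, downstream, dual_vae, evaluation, privacy, simulate
from .config import (ExperimentConfig, load_params_into, save_params,
                     stage_seed, version_manifest)
from .dp import DPConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _write_report(path: Path, payload: dict, config: ExperimentConfig) -> None:
    payload = {"manifest": version_manifest(config), **payload}
    path.write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def run_pipeline(config: ExperimentConfig) -> Path:
    """Execute every enabled stage; returns the artifacts directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: data (simulate or load) -----------------------------------
    try:
        if config.data.input_archive:
            batch, manifest = data.read_archive(config.data.input_archive)
            if manifest is None:
                raise ValueError("input archive lacks a manifest sidecar")
            sim_cfg = None
        else:
            s = config.simulate
            sim_cfg = simulate.SimulatorConfig(
                n_patients=s.n_patients, T=s.T, dim_cont=s.dim_cont,
                dim_disc=s.dim_disc, latent_dim=s.latent_dim,
                ar_coef=s.ar_coef, noise_sd_cont=s.noise_sd_cont,
                seed=stage_seed(config.seed, "simulate"))
            batch = simulate.simulate_batch(sim_cfg)
            manifest = simulate.make_manifest(sim_cfg, batch)
        plan = data.split_dataset(batch,
                                  {"train": config.data.train_fraction,
                                   "test": 1 - config.data.train_fraction},
                                  seed=stage_seed(config.seed, "split"))
        batch_std = data.standardize(batch, manifest, plan.train)
        data.write_archive(batch, out / "real.npz", manifest)
    except Exception as e:
        raise StageError("data", e) from e

    # ---- stage: pretrain ---------------------------------------------------
    try:
        v = config.dual_vae
        weights = dual_vae.LossWeights(
            beta_kl=v.beta_kl, beta0=v.beta0, beta1=v.beta1, beta2=v.beta2,
            beta3=v.beta3, tau=v.tau)
        if config.adversarial.ablation == "gan_vae":
            weights.beta1 = weights.beta2 = 0.0
        vcfg = dual_vae.VAEConfig(
            latent_dim=v.latent_dim, hidden=v.hidden, lr=v.lr,
            batch_size=v.batch_size,
            tie_weights=config.adversarial.ablation != "gan_vae",
            conditional=config.adversarial.conditional,
            n_labels=0 if batch.labels is None else batch.labels.shape[1])
        train_batch = batch_std.subset(plan.train)
        ckpt = out / "vae.npz"
        if ckpt.exists():
            rng = np.random.default_rng(stage_seed(config.seed, "pretrain"))
            vae = dual_vae.VAEParams(rng, batch.dim_cont, batch.dim_disc, vcfg)
            load_params_into(vae, ckpt)
            curves = None
        else:
            vae, curves = dual_vae.pretrain(
                train_batch, weights, vcfg, epochs=v.epochs,
                seed=stage_seed(config.seed, "pretrain"))
            save_params(vae, ckpt, {"stage": "pretrain",
                                    **version_manifest(config)})
            _write_report(out / "pretrain_curves.json", {"curves": curves}, config)
    except Exception as e:
        raise StageError("pretrain", e) from e

    # ---- stage: adversarial training --------------------------------------
    try:
        a = config.adversarial
        dp_cfg = None
        if a.dp_clip_norm is not None:
            dp_cfg = DPConfig(clip_norm=a.dp_clip_norm,
                              noise_multiplier=a.dp_noise_multiplier,
                              delta=a.dp_delta,
                              target_epsilon=a.dp_target_epsilon)
        tcfg = adversarial.TrainConfig(
            epochs=a.epochs, batch_size=a.batch_size, lr_gen=a.lr_gen,
            lr_disc=a.lr_disc, hidden=config.generator.hidden,
            noise_dim=config.generator.noise_dim,
            decoder_finetune=a.decoder_finetune, ablation=a.ablation,
            conditional=a.conditional, dp=dp_cfg,
            seed=stage_seed(config.seed, "gan"))
        if dp_cfg is not None:
            gen, disc, log, dp_report = adversarial.dp_train_gan(
                train_batch, vae, tcfg)
            _write_report(out / "privacy_budget.json", dp_report, config)
        else:
            gen, disc, log = adversarial.train_gan(train_batch, vae, tcfg)
        save_params(gen, out / "generator.npz",
                    {"stage": "gan", **version_manifest(config)})
        with open(out / "train_log.jsonl", "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    except Exception as e:
        raise StageError("train", e) from e

    # ---- stage: generate ---------------------------------------------------
    try:
        n_b = len(plan.subtrain)
        labels = None
        if a.conditional and batch.labels is not None:
            rng = np.random.default_rng(stage_seed(config.seed, "genlabels"))
            labels = batch.labels[rng.integers(batch.n, size=n_b)]
        synth = adversarial.generate(
            n_b, vae, gen, labels=labels, manifest=manifest,
            seed=stage_seed(config.seed, "generate"))
        plan.synthetic = synth
        data.write_archive(synth, out / "synthetic.npz", manifest)
    except Exception as e:
        raise StageError("generate", e) from e

    # ---- stage: evaluate ---------------------------------------------------
    report = {}
    if config.evaluation.enabled:
        try:
            heldout = batch.subset(plan.subtest)
            n_eval = min(heldout.n, synth.n)
            rep = evaluation.evaluate(
                heldout.subset(np.arange(n_eval)),
                synth.subset(np.arange(n_eval)),
                seed=stage_seed(config.seed, "evaluate"),
                disc_epochs=config.evaluation.disc_epochs,
                disc_seeds=config.evaluation.disc_seeds,
                stride_hours=config.evaluation.stride_hours)
            report["evaluation"] = rep.to_dict()
            _write_report(out / "evaluation.json", report["evaluation"], config)
        except Exception as e:
            raise StageError("evaluate", e) from e

    # ---- stage: downstream utility -----------------------------------------
    if config.downstream.enabled:
        try:
            d = config.downstream
            channel = d.channel or batch.feature_names_disc[0]
            scenarios = []
            for m in d.scenarios:
                if m.startswith("TSRTR"):
                    scenarios += [downstream.AugmentationScenario(m, r)
                                  for r in d.ratios]
                else:
                    scenarios.append(downstream.AugmentationScenario(m))
            rows = downstream.run_utility_suite(
                batch, plan, channel, scenarios, repeats=d.repeats,
                seed=stage_seed(config.seed, "downstream"),
                predictor_kwargs={"epochs": d.epochs}, skip_degenerate=True)
            report["downstream"] = rows
            _write_report(out / "downstream.json", {"rows": rows}, config)
        except Exception as e:
            raise StageError("downstream", e) from e

    # ---- stage: membership attack ------------------------------------------
    if config.privacy.enabled:
        try:
            mask = np.zeros(batch.n, dtype=bool)
            mask[plan.train] = True
            res = privacy.membership_attack(privacy.AttackSetup(
                candidates=batch, member_mask=mask, synthetic=synth))
            report["privacy"] = {"accuracy": res.accuracy, "recall": res.recall}
            _write_report(out / "privacy_attack.json", report["privacy"], config)
        except Exception as e:
            raise StageError("attack", e) from e

    _write_report(out / "report.json", report, config)
    return out
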