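# mtsgan

Synthesis of **mixed-type clinical timeseries** — paired continuous-valued
physiological channels and binary intervention channels on a fixed hourly
grid — with a built-in evaluation battery covering fidelity, cross-type
correlation, downstream utility, and privacy.

Who this is for: researchers who need realistic, shareable stand-ins for
ICU-style longitudinal EHR cohorts (vitals + treatment switches), and who
need to *measure* whether a generator's output is statistically faithful,
useful for training predictors, and non-memorizing.

## The model

Generating binary treatment sequences with a GAN is awkward because hard
0/1 outputs break the gradient path. The stack here sidesteps that by
training the GAN entirely in a learned latent space:

1. **Dual VAE, shared latent space.** Two recurrent variational
   autoencoders — one per data type — encode a patient's continuous series
   x^C_{1:T} and discrete series x^D_{1:T} into per-timestep Gaussian
   posteriors in one space H^S. The pretraining objective per domain d is

   L_d = β₀·L^ELBO_d + β₁·L^Match + β₂·L^Contra (+ β₃·L^Class_d),

   where L^Match = E‖z^C_t − z^D_t‖² aligns the two views of one patient,
   L^Contra is the NT-Xent contrastive loss over temporally pooled
   embeddings (positive pair = the two views of one patient), and the
   optional semantic term is the cross-entropy of a linear probe on the
   pooled latent against condition labels. Latent-adjacent layers are
   weight-tied across domains.

2. **Coupled recurrent generator.** Two bilateral-LSTM (BLSTM) streams map
   paired uniform noise sequences υ^C, υ^D to paired latent trajectories;
   every gate of stream d also sees the previous hidden state of the
   *other* stream, so the generated trajectories can carry the cross-type
   dependence present in real data. Zeroing those cross-weights reduces
   each stream exactly to a vanilla LSTM (tested to 1e-12).

3. **Adversarial training.** Generated latents are decoded by the frozen
   pretrained decoders; one LSTM discriminator per data type scores whole
   sequences; the generator minimizes the non-saturating GAN loss summed
   over domains. The discrete path stays differentiable by feeding the
   decoder's Bernoulli probabilities to the discriminator; thresholding
   happens only at sampling time. Optional: conditional generation (labels
   concatenated everywhere) and DP-SGD with an RDP accountant.

Evaluation: unbiased MMD² with a summed Gaussian kernel on per-patient
T×|J| matrices; dimension-wise Bernoulli probabilities (RMSE/CC);
a post-hoc Bi-LSTM discriminative score; per-timepoint trajectory
summaries; pairwise-correlation heatmaps compared via CorAcc (fraction of
entries in the same correlation bin) and μ_abs; ACF curves; TRTR/TSTR/
TSRTR macro-AUROC for 12 h→12 h intervention-status prediction; black-box
membership inference.

All recurrent networks run on a small reverse-mode autodiff engine over
numpy (`mtsgan.autodiff`) — the package has no deep-learning-framework
dependency.

## Worked example

A built-in simulator provides ground truth: a shared stationary AR(1)
latent health state drives both the vitals (linear read-out + noise) and
the interventions (logistic read-out), so cross-type coupling is real and
its moments are known in closed form.

```bash
python examples/02_train_and_generate.py
```

prints (one CPU, ~2 min):

```
pretraining: total loss 244.6 -> 122.8 over 40 epochs
adversarial: disc loss 2.867 -> 2.746, gen loss 1.631

generated 240 synthetic records
  continuous mean/SD: -0.69 / 1.70 (real: 0.05 / 1.85)
  intervention rate:  0.58 (real: 0.51)

MMD^2 (continuous channels): 2.789  (0 = indistinguishable)
discriminative score: 0.906  (0.5 = critic cannot tell them apart)
```

The synthetic marginals track the real ones; at this desk scale the critic
can still separate real from synthetic (score above 0.5), which is exactly
what the fidelity battery is there to quantify. The other examples cover
the simulator oracles (`01`), the metric battery on calibration cases
(`03`), TSTR utility ceilings/floors (`04`), membership inference (`05`)
and DP training (`06`). A thin CLI wraps the pipeline:
`mtsgan run --config config.yaml`.

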