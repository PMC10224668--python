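# Desk-scale end-to-end configuration: simulate -> pretrain -> adversarial
# training -> generate -> evaluate -> downstream utility -> membership attack.
# Runs in a few minutes on one CPU:  mtsgan run --config examples/config_smoke.yaml
seed: 0
output_dir: mtsgan_smoke_run
simulate:
  n_patients: 240
dual_vae:
  hidden: 32
  latent_dim: 4
  epochs: 40
  batch_size: 32
generator:
  hidden: 32
adversarial:
  epochs: 40
  batch_size: 32
evaluation:
  disc_epochs: 20
  disc_seeds: 1
downstream:
  enabled: true
  scenarios: [TRTR, TSTR]
  repeats: 2
  epochs: 20
privacy:
  enabled: true
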