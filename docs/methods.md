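# Methods

## Problem setting and data model

A record is one patient's fixed-length window: `T` regularly spaced bins
(default 24, read as hourly bins with index 0 the earliest), `|J|`
continuous physiological channels and `|K|` binary intervention channels,
optionally a one-hot condition label. Inputs must be complete; the readers
reject missing cells rather than impute, because imputation belongs to the
upstream extraction pipeline and silently filling values here would blur
what the generator was actually trained on. Continuous channels are
z-scored per feature using statistics of the generator-training split only
(stored in the dataset manifest so generated output can be mapped back to
original units without test-set leakage).

## Synthetic cohort simulator

The simulator is first-class, tested code: it defines the study conditions
under which every stage of the stack is exercised, since real credentialed
ICU cohorts are out of scope.

Per patient, a latent health state `s_t` (dimension 2 by default) follows
a stationary Gaussian AR(1): `s_t = a·s_{t−1} + ε_t`, `ε_t ~ N(0, I)`,
`s_1 ~ N(0, 1/(1−a²)·I)`, with `a = 0.8` — strong hour-to-hour
persistence, the regime where temporal structure actually matters.
Continuous channels are `x^C_t = Λ_C s_t + η_t`, `η_t ~ N(0, 0.5²)`; each
of the 5 default channels loads 1.0 on one latent dimension and 0.3 on the
next (deterministic, non-degenerate pattern). Binary channels are
Bernoulli with log-odds `Λ_D s_t + b`, each of the 2 default channels
loading 2.0 on one latent dimension with zero intercept, giving activation
rates near 0.5 and a real, recoverable cross-type correlation with the
vitals that share its latent dimension. Two outcome classes are assigned
by thresholding the patient's mean latent trajectory at 0.

Dimensions (5 continuous / 2 discrete, N in the hundreds) are desk-scale
choices: large enough that cross-type structure is measurable, small
enough that the full stack trains in minutes on one CPU. What the
simulator does **not** emulate: heavy-tailed or multimodal vital
distributions, irregular sampling, missingness, regime switches around
interventions (interventions here do not feed back into the latent
state), or high-dimensional sparse channels. Passing tests therefore
demonstrate correctness of the machinery and recovery of linear-Gaussian
cross-type structure — not clinical realism.

Closed-form oracles used by the tests: stationary variance `1/(1−a²)` per
latent dimension, process autocorrelation `a^h`, observed-channel ACF
shrunk by the signal-to-total-variance ratio, and Monte-Carlo Bernoulli
rates (1e5 draws, seeded). The per-patient sample ACF over a 24-bin window
carries the usual finite-window negative bias, so oracle tests use the
ensemble estimator (correlating `x_t` with `x_{t+h}` across patients);
the evaluation battery compares real and synthetic with the *same*
per-patient estimator, so its bias cancels in the comparison.

## Dual-VAE pretraining

Encoders and decoders are single-layer LSTMs (hidden 64 by default; many
tests use 32) with linear heads. The encoder emits a per-timestep Gaussian
posterior (mean, log-variance) in the shared latent space (default
dimension 4); sampling uses the reparameterization path. The decoder
projects the latent through a tanh bottleneck into an LSTM and emits
continuous values or Bernoulli logits.

Losses, per batch (means over patients, sums over time/dims):

* **ELBO**: unit-variance Gaussian likelihood for continuous channels
  (reconstruction = ½·squared error) and Bernoulli likelihood for binary
  channels (cross-entropy via a numerically safe logit form), plus the
  closed-form KL to N(0, I) weighted by `β_KL` (default 1).
* **Matching**: mean over patients of Σ_t ‖z^C_t − z^D_t‖² on posterior
  means.
* **Contrastive**: NT-Xent (temperature τ = 0.5) over the 2N temporally
  mean-pooled posterior means; pooling over time is the simplest
  order-invariant reduction and is the package's choice where the
  per-patient embedding was otherwise unspecified.
* **Semantic** (conditional mode): cross-entropy of a linear head on the
  pooled latent against the one-hot label.

The joint objective counts the shared matching/contrastive terms once:
`β₀(ELBO_C + ELBO_D) + β₁·Match + β₂·Contra (+ β₃(Class_C + Class_D))`,
with defaults β₀ = β₁ = 1, β₂ = β₃ = 0.1. Summing two per-domain totals
would double the shared terms; the single-count convention reaches the
same optimum and makes the reported loss components unambiguous.

**Weight sharing.** The latent-adjacent layers are tied across domains:
both encoders share their mean and log-variance heads, both decoders share
the latent input projection. Tying is implemented by object identity (one
parameter tensor, two layers), so the tied copies are bit-identical by
construction after every update; gradients from both domains accumulate
into the shared tensor.

**KL warm-up.** `β_KL` is annealed linearly from 0 over the first half of
pretraining (`kl_warmup_frac = 0.5`). Without it the binary-channel
decoder reliably collapses onto the prior at desk scale — its
reconstruction term (a few dozen bits) is small against the KL over
`T × |S|` dimensions, and the decoder learns to ignore its latent, which
destroys the cross-type structure everything downstream depends on. The
annealed objective equals the configured one from mid-training onward.

Optimizer: Adam, lr 1e-3. Batch size default 128; test-scale runs use 32
because at N in the low hundreds the update count, not the epoch count,
governs convergence.

## Coupled generator and adversarial stage

The bilateral-LSTM cell follows the standard LSTM gate algebra except that
every gate of stream d receives three linear terms: the noise input
`υ_t^d`, the own previous hidden state `h^d_{t−1}`, and the *counterpart*
stream's previous hidden state `h^{d′}_{t−1}`. Two such streams unrolled
from zero state over independent per-timestep U(0,1) noise (dimension =
latent dimension by default; a fixed-per-sequence noise mode is available
behind a flag), followed by per-stream linear projections, emit the paired
synthetic latent trajectories. Zeroing the cross-weights recovers two
independent vanilla LSTMs exactly — the structural reduction test — and is
how the uncoupled ablations (`gan_vae`, `gan_sl`) are trained (pinned to
zero after every update; `gan_vae` additionally pretrains the VAEs
independently: no tying, β₁ = β₂ = 0).

Discriminators are per-type LSTMs with a sigmoid head on mean-pooled
hidden states. Training alternates single discriminator and generator
steps (Adam, lr 1e-3 both). Losses are computed in logit space (softplus
form), so the objective stays finite even when a discriminator saturates;
the generator uses the non-saturating form. Decoders stay frozen during
adversarial training by default: the discrete path's differentiability
argument rests on the decoder's probability outputs, and fine-tuning them
against the discriminator can drift the latent→observation mapping the
pretrained encoders defined. The discriminator sees decoder probabilities
for the discrete stream during training; hard 0.5 thresholding (or
Bernoulli sampling, behind a flag) is applied only when materializing
synthetic records. For correlation evaluation the Bernoulli mode is the
faithful choice: thresholding a probability that hovers near one side
collapses a channel to a constant and erases the correlation signal being
measured.

## Differential privacy

DP-SGD applies to every optimizer that touches real data — the
discriminators (and pretraining when run under the DP path): per-sample
gradient clipping at `C`, Gaussian noise with SD `noise_multiplier · C`
added to the summed gradient. Per-sample gradients are obtained by
backpropagating each record's loss separately (exact, at a runtime cost —
DP runs are kept small). The accountant tracks Renyi DP of the subsampled
Gaussian mechanism at integer orders 2–64 via the binomial-expansion
bound, composes linearly over steps, and converts to (ε, δ) at δ = 1e-3 by
minimizing over orders. ε is monotone in steps and decreasing in the noise
multiplier (property-tested); a target ε stops training when the budget is
exhausted.

## Evaluation battery

* **MMD**: unbiased estimator of squared MMD between per-patient `T×|J|`
  matrices under a summed Gaussian kernel
  `K(x, x′) = Σ_i exp(−‖x−x′‖²_F / σ_i²)`; bandwidths default to the
  median pairwise Frobenius distance × {0.25, 0.5, 1, 2, 4}. The unbiased
  estimator is legitimately slightly negative under the null (O(1/n));
  report validation allows that.
* **Dimension-wise probability**: per-(channel, bin) activation rates,
  compared by RMSE and unclipped Pearson correlation; a constant rate
  vector makes the correlation undefined and is flagged rather than
  clamped.
* **Discriminative score**: a freshly initialized single-layer Bi-LSTM
  critic (hidden 32, Adam 1e-3, 50 epochs — the package's settings where
  only the architecture class was prescribed) labels real = 1 /
  synthetic = 0 on the concatenated channels, stratified 80/20 split,
  held-out accuracy averaged over seeds.
* **Correlation**: Pearson correlations between all (feature,
  every-3rd-bin) columns, both data types as numeric columns;
  zero-variance columns get zero correlations and a warning. CorAcc is
  the fraction of off-diagonal entries whose two heatmaps fall in the same
  correlation level among the seven intervals
  [−1,−.5), [−.5,−.3), [−.3,−.1), [−.1,.1), [.1,.3), [.3,.5), [.5,1];
  μ_abs is the mean absolute off-diagonal difference. Diagonals are
  excluded (trivially 1 in both).
* **ACF**: per-patient sample ACF per feature at lags 0..T−1, averaged
  across patients (equal patient weight), constant series excluded with a
  reported count; RMSE between the real and synthetic averaged curves.
* **Utility**: 12 h observation → 12 h prediction of one intervention
  channel, four outcome classes anchored at the first prediction bin
  (begins-on and stays on = Stay on; begins-on, off at some point =
  Switch off; begins-off, on at some point = Onset; else Stay off) — an
  exhaustive partition of all 2¹² windows, verified by enumeration.
  Regimes: TRTR (train on real sub-train A′_Tr), TSTR (train on synthetic
  B with labels derived from B's own generated intervention channel),
  TSRTR-α (A′_Tr plus an α-fraction of B), TSRTR-β (B plus a β-fraction
  of A′_Tr); test always on the held-out real A′_Te. The 70/30 split
  halves the held-out set; stratified by label when present. Predictor: a
  1-layer LSTM (hidden 64, 50 epochs) over the continuous channels only;
  macro-AUROC over classes present in the test labels. Scenario means are
  compared to TRTR with an unpaired t-test at α = 0.05.
* **Membership inference**: nearest-synthetic-record distance
  (standardized Euclidean on flattened continuous channels + Hamming on
  discrete, weights 1:1), quantile-calibrated to the true member fraction,
  ties broken by (distance, index). A memorizing generator is caught
  exactly; a membership-independent source drives accuracy to 0.5.

## Problem sizes in the test suite

The directional ablation check (full model vs uncoupled `gan_vae` on
cross-type CorAcc) runs at N = 240, hidden 32, 40 pretraining + 40
adversarial epochs, batch 32, averaged over seeds 0–2, with Bernoulli
sampling of the discrete channels — the smallest configuration at which
the dual-VAE reconstructs near the simulator's noise floor and the
comparison measures signal rather than a degenerate constant channel. The
acceptance script's null calibrations use 500 + 500 records (critic) and
400 + 400 (attack). These sizes are the package's desk-scale defaults;
conclusions about large cohorts require scaling them up.

## Known limitations

* The adversarial objective factorizes over the two data types (one
  discriminator each), so nothing *forces* the generated latent streams
  into the sign-aligned joint distribution of real pairs; the cross-type
  dependence of synthetic output rests on the architecture's inductive
  bias (cross-stream recursion + shared decoder geometry). At desk scale
  the resulting cross-type correlation advantage of the coupled generator
  over the uncoupled ablation is real but small.
* Fixed-length sequences only; no missingness, no irregular sampling.
* DP per-sample gradients are computed by looping over records —
  exact but slow; DP runs should stay small.
* The reverse-mode engine is float64 single-threaded numpy; it favors
  determinism and auditability over speed.
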