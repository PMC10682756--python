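# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the test suite does and does not establish.

## Personalized encoder

The backbone is a pre-LN transformer encoder over frame sequences
(`EncoderConfig`): input projection to width `h`, sinusoidal positions
(switchable), `L` layers of multi-head self-attention and GeLU feedforward,
a final layer norm, temporal mean pooling and an affine regression head.
A full-scale pretrained speech encoder is out of scope; desk defaults
(`L=4, h=64`, experiments use `L=2, h=16`) keep single-CPU runs fast while
preserving the architecture.

Personalization inserts a bottleneck adapter after the attention block and
after the feedforward block of every layer, before the residual addition:

    A(x) = LN(U(GeLU(D(x)))) + x,   LN(x) = (x − μ)/σ ⊙ γ + β,

with D: h→d, U: d→h and the LN statistics taken across the `h` channels of
each position. All adapter parameters are generated per subject by one
shared hypernetwork set:

    I_S = h_I(concat(m_S, l_i, p_j))          (FC+ReLU, then linear FC)
    (W_D, b_D), (W_U, b_U) = h_D(I_S), h_U(I_S)
    (β, γ) = h_LN(I_S)

`l_i` (one row per layer) and `p_j` (two rows: post-attention,
post-feedforward) are learned embedding tables; only those tables grow with
depth — the generators are shared across all `2L` sites. The generators are
affine (weight and bias); a pure-matrix generator is recovered by
zeroing the biases. Tunable dimensions (`d=8, s=8, e=8` by default, smaller
in the experiments) are free parameters of this artifact; no reference
values exist for them.

Numerical choices:

* `ln_eps = 1e-5` inside the LN denominator so that constant vectors (in
  particular the all-zero vector produced at initialization) normalize
  finitely. This makes the **identity-at-init** property exact: generator
  output layers (weights *and* biases) start at zero, every adapter is the
  identity, and the personalized forward equals the frozen baseline's
  bit-for-bit.
* The regression head's bias is initialized to the training-target mean.
  Checkpoint selection uses a rank correlation, which is blind to output
  scale; without mean-calibrated starting predictions, a rank-accurate but
  scale-uncalibrated early checkpoint can win selection and ruin MAE.
* Everything runs in float64 on a minimal reverse-mode autodiff engine
  (`autodiff.py`); gradients are verified against central finite
  differences in the test suite.

## Baselines and training protocol

`baselines` provides the 3-hidden-layer ReLU FFNN on functional features
(hidden width 30; 256 intended for encoder embeddings), its additive-
metadata variant (zero-initialized linear projection of `m_S` added to the
second hidden layer, hence exactly the plain FFNN at start), and full
fine-tuning of the adapter-free encoder.

`training` implements speaker-independent, group-stratified 5-fold CV with
a validation fifth split from each training side (never from test), AdamW
with linear warmup (default 10% of steps, constant at peak afterwards),
MSE loss on the 0–10 target (L1 available), and per-epoch checkpointing
with selection by **global** Spearman correlation on the validation set.
Freeze policies per model kind are enforced by disabling gradient tracking,
so the frozen partition provably accumulates zero gradient. Defaults follow
the study protocol (encoder paths: batch 16, lr 3e-4, ≤10 epochs; FFNNs:
batch 128, lr 1e-4, ≤100 epochs); the benchmark experiments override batch
size, epochs and learning rate for desk scale (below).

## Synthetic cohort

`synth_cohort` samples three screening groups — 47 controls (PHQ-9 ≤ 4,
enforced by rejection-resampling), 48 subclinical (PHQ-9 > 4), 48 patients —
with demographics and five item-level instruments (HRSD-24, PHQ-9, BDI,
SEK-27, TIPI). A single latent severity scalar per subject (group means
−1.5 / −0.1 / +1.0, SD 0.5) drives all depression-instrument item means, so
instrument totals are mutually correlated; SEK items load negatively on
severity by default (higher score = better regulation; the sign is a config
knob because the empirical direction is not settled here). A second latent,
the **psychomotor expression subtype** `a_S = tanh(1.2·N(0,1)) ∈ (−1,1)`
(retarded vs agitated), shifts the means of the two HRSD psychomotor items
(retardation up, agitation down by `1.4·a_S`), making the subtype decodable
from clinician-rated metadata. Per-subject RNG substreams are keyed by
(seed, subject id), so enlarging a cohort never perturbs existing subjects.

## Synthetic EMA

`synth_ema` generates the 14-day × 3-sessions × (3 contents × 3 repetitions)
schedule (378 recordings, 42 ratings per complete participant), with whole
sessions dropped Bernoulli-wise at group rates 169/1974, 200/2016, 233/2016
(the emulated protocol's per-group missing-session counts over the per-group maxima).

Mood is `clamp(round(μ_S + AR1_t + ε_t), 0, 10)` with
`μ_S = 2.8 + 1.4·severity + N(0, 1.0)`, AR(1) persistence φ=0.5
(innovation SD 0.9) and white noise SD 0.6. The variance split was
calibrated once: the cohort-level Spearman between mean mood and PHQ-9
total lands at ≈0.74–0.83 (the targeted moderate-to-strong range), while
within-person variance stays a large enough share that rank-based model
selection is sensitive to within-person skill.

Features (f0_mean, hnr, jitter, shimmer, nsyll, npause, duration,
speech_rate) follow

    feature_k = trait_k·severity_S + intercept_{S,k}
                + sign_k · strength_k · content_gain_k(content)
                  · attenuation_k(S) · style_k(S) · z_S(t) + noise,

where `z_S(t)` is the subject's within-person standardized mood. The pieces
encode, in order:

* **trait loadings** — severity shows in the voice at the trait level
  (lower HNR, higher jitter/shimmer, slightly lower F0 in more severe
  subjects), so between-subject feature levels carry diagnostic but no
  mood-change information;
* **state couplings** — lower F0, more syllables and pauses, longer
  duration, lower rate when currently more depressed (signs fixed,
  magnitudes 0.6–0.8 for prosodic/timing features, 0.1 for voice quality);
* **content gains** — full strength for free answers, 0.6 for positive
  thoughts; read questions retain only half the F0 coupling and almost none
  of the timing coupling (their wording is fixed);
* **attenuation** — subjects with above-cohort-median PHQ-9 express mood
  more weakly (per-feature multipliers 0.5–0.7);
* **psychomotor style** — the timing-feature couplings are multiplied by
  the signed subtype `a_S`: retarded expressors slow down when depressed,
  agitated expressors speed up. A population model fitted across subjects
  averages these couplings toward zero; a model conditioned on metadata
  (the HRSD psychomotor items) can recover them per subject. This axis is
  what gives *zero-shot* personalization genuine, decodable headroom.

Frames mode emits T noisy copies of the functional vector (frame noise SD
0.5), so temporal mean pooling recovers it in expectation.

`estimate_feature_mood_coupling` z-scores mood and features within speaker,
pools all rows and returns the OLS slope (cov/var computed from first
principles) with a normal-approximation CI; speakers with constant mood are
excluded and reported. Under z-scoring of both sides the estimand for
coupling `b = sign·strength·gain` and noise SD σ is `b/√(b²+σ²)`, and the
parameter-recovery check compares against exactly that closed form.

## Metadata encoding

Item-level encoding (each item one continuous entry, z-scored with
statistics fitted on training-fold subjects only; constant fields keep
scale 1), age continuous, degrees ordinal scaled to [0,1], gender one-hot
(m/f/diverse), employment and medication binary. Named subsets mirror the
ablation design: `phq9` (9), `hrsd` (24), `bdi` (21), `sek` (27),
`personality` (10), `depression_tests` (54), `demographics_medication` (9),
`all` (100). Instrument totals can be appended behind a flag (off by
default). The API takes explicit subject lists per fold role, so test-fold
information cannot leak into the normalizer. Missing metadata raises; no
imputation is provided (synthetic data is complete).

## Benchmark experiments

The personalization benchmark (`experiments.run_personalization_trial`)
uses a 90-subject cohort (30 per group), one recording per content type per
session, six frames per recording, and a 2-layer, width-16 encoder — sizes
chosen so the five-seed benchmark completes in a few minutes on one CPU.
Per seed, three of the five CV folds are trained and averaged (the study
protocol averages over folds): fine-tuned encoder first (6 epochs, lr 1e-3,
batch 64, AdamW wd 0.01), then the hyperformer initialized from its frozen
weights (14 epochs, lr 2e-3, warmup 0.3). Reported: mean per-speaker ρ and
MAE for both models, Gini over speaker-level ρ (all speakers and patients
only; the raw formula, falling back to the clip-at-zero variant if the mean
is non-positive), and winners/losers.

The level-shift experiment isolates the known failure mode of additive
metadata fusion: with state couplings and trait loadings zeroed, the voice
stream is pure noise and metadata predicts only each subject's mean mood.
The additive FFNN then cuts global MAE substantially while mean per-speaker
ρ stays at chance — level personalization without any gain in mood-change
tracking.

## What passing tests show — and what they do not

The suite establishes that the implementation is faithful (oracle
equivalence of every numeric primitive and of the full personalized forward
pass, exact identity at initialization, an exactly-zero gradient norm on
the frozen backbone) and that the *mechanism* behaves as designed on data
whose individual differences are metadata-decodable by construction: the
hyperformer beats the fine-tuned encoder on per-speaker ρ, improves most
speakers, does not increase performance inequality, and the content-type
gradient (answer > positive thought > question) emerges.

None of this is evidence about real speech. The generator's features are
conditionally Gaussian summaries with linear mood coupling; real acoustic
functionals are heavier-tailed, autocorrelated within sessions, and their
coupling to mood is certainly weaker and messier than the constructed
psychomotor axis. Absolute metric values (ρ ≈ 0.29 → 0.34 here) therefore
carry no clinical meaning; only the *directions* of the comparisons are the
point. Missingness is independent of mood by design, linguistic content is
not modeled, and metadata are complete — all of which flatter any
metadata-conditioned method relative to field conditions.

## Known limitations

* The autodiff engine supports exactly the operations these models need; it
  is not a general-purpose framework (no convolutions, no dropout).
* Checkpoint selection by global validation Spearman — kept for protocol
  fidelity — is a blunt instrument for personalization: it weighs
  between-subject ordering far more than within-subject skill. The
  mean-initialized head mitigates its scale-blindness; the residual
  selection noise is why benchmark claims are made over seeds and folds,
  not single runs.
* `make_splits` requires at least `k` subjects per group for stratification.
* Real-data loading (`cohort_from_frame`, `EmaDataset` tables) expects the
  documented column layout and raises on missing metadata rather than
  imputing.
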