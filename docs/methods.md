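# Methods

## Task and model

Patient–trial matching is cast as binary classification of `<EHR,
Criteria>` pairs: given a patient's record and a trial's list of
inclusion/exclusion statements, predict eligibility (success = 1,
fail = 0).  The core model is a siamese network: one encoder f_θ, applied
to both the EHR representation and the criteria representation, whose two
outputs are fused and scored by a one-unit sigmoid head.  Weight sharing
is structural — both branches literally run through the same parameter
tensors — so gradients from either branch update the one encoder, and the
model learns cross-branch correlations rather than two independent
feature extractors.  The early-fusion comparison model concatenates the
pair on the input side and trains a single encoder of the same family on
the merged input.

## Embeddings

Two granularities are supported.  Coarse: one vector per document; the m
criterion statements are embedded independently and mean-pooled into one
trial vector.  Fine: one vector per token; the criterion statements are
concatenated in listed order without separator tokens (the simplest
faithful composition; nothing in the task fixes a separator convention).
Token sequences are capped at 512 tokens (tail truncation) to bound
memory.

Embedding providers are pluggable.  The default `HashedRandomProvider`
maps each text (or token) to a unit vector drawn from a generator seeded
by a SHA-256 hash of the text plus the provider seed: deterministic across
processes and platforms, no network, no model weights.  It preserves
*identity* structure (same text → same vector, distinct texts → distinct
vectors) but no *semantic* structure; semantic signal in the test beds
comes from the synthetic generator below.  A real LM backend implements
two methods (`embed_text`, `embed_token`); document embeddings from such a
backend are conventionally the mean of final-layer token states.

## Encoders

| family | input | output width F | notes |
|---|---|---|---|
| mlp | vector | projection_dim (default 64) | per hidden layer: affine → batch norm → ReLU → dropout (0.1); 1–4 layers of 50 units |
| lstm / gru | sequence | H (default 50) | final hidden state readout; dropout 0.5 on the readout |
| bilstm / bigru | sequence | 2H | concatenated final forward/backward states |
| *_att variants | sequence | H or 2H | additive self-attention: softmax(H·u) over positions, convex combination of hidden states |
| cnn | sequence | filters K (default 64) | 1-d convolution (kernel 3, unit stride, no padding) → ReLU → mean-pool over valid positions |
| cnn_lstm | sequence | H | CNN feature sequence (no pooling) fed to an LSTM |

Non-attention recurrent readout is the final state, the standard choice
when nothing else is specified; attention variants replace it with the
attention-weighted sum.  Variable-length batches are tail-padded with a
mask; masked positions are frozen out of the recurrent state update,
excluded from the attention softmax, and excluded from CNN mean-pooling
(a convolution window is valid only if it covers real tokens).  The
defaults (H = 50, dropout 0.5 recurrent / 0.1 MLP, projection 64, CNN
K = 64 / kernel 3) are the hyperparameters the evaluation protocol uses
throughout.

All networks run on `trialmatch.autodiff`, a small numpy reverse-mode
engine (float64, per-step tape).  Parameters initialize Glorot-uniform
from a generator seeded by the encoder config seed; dropout masks come
from a separate stream so evaluation never perturbs training randomness.

## Objectives

Losses are written as sums over the cohort; training defaults to the mean
reduction so the fixed learning rate (0.005) is insensitive to fold size,
and the sum form is available for closed-form checks.  Probabilities are
clamped to [1e−7, 1−1e−7] before the log.  WBCE multiplies only the
positive-class term by β; β defaults to N_fail/N_success computed on the
training split of each fold (≈ 2.6 at the default 50/130 imbalance), never
on test data.  The contrastive loss uses cosine similarity d_w of the two
branch encodings with a squared hinge at margin 1.0 — the largest
attainable cosine similarity, so the hinge is active everywhere below
perfect alignment.  The printed form penalizes (1−y)·d², which also pushes
negative similarities toward zero; it is implemented exactly so.  Because
the contrastive objective never trains the output head, inference
thresholds d_w at margin/2.  Cosine of a zero vector raises an error
rather than returning 0: a collapsed encoder should fail loudly.

## Evaluation protocol

Stratified 5-fold cross-validation (shuffled, seeded); with 180 samples at
50/130 this forces test folds of 36 with exactly 10 eligible.  Per fold a
fresh model trains with Adam (lr 0.005) for 50 epochs — full batch for
coarse input, batches of 16 for fine input.  Ten percent of each fold's
training split is held out to record a validation-loss history for
monitoring only; the final model is always the epoch-50 model, keeping the
fixed-epoch protocol honest.  Metrics per fold: confusion counts, F1 of
each class, and macro-F1 (the mean of the two class F1s) as the headline
"F1"; the eligible-class F1 ("F1-Pos") is always reported separately
because it is the recruitment-relevant number.  Model comparison is a
paired per-fold test: identical fold structure required, per-fold F1
deltas, relative gain (mean_A − mean_B)/mean_B, and a two-sided paired
t-test (a documented stand-in, since small k makes any test approximate);
zero-variance deltas return p = 1 with a warning instead of NaN.

One run seed fans out to fold assignment, data generation, parameter
initialization, dropout and shuffling; the full pipeline is bit-stable
given the seed, and every report and artifact records its seed and config.

## Rule-based baseline

Institutional cohort queries are replaced by a portable predicate DSL over
structured records (coded events of six types, age, gender): `has_code`,
`numeric_threshold`, `age_range`, `gender_is`, each tagged inclusion or
exclusion.  Feature extraction returns the *raw* truth value of every
predicate as a binary indicator (exclusions are not negated; the
classifier learns the sign), and logistic regression / SVM / random
forest run with library-default hyperparameters and a fixed seed under
the same folds and metrics as the neural models.

## Synthetic cohorts

The generator emulates a small single-trial cohort; its defaults are the
study conditions used throughout the tests: 180 pairs, 50 eligible / 130
not, embedding dimension 64, coupling s = 0.9, spherical Gaussian noise
σ = 0.1, token lengths uniform on [5, 30].

Coarse mode draws one latent trial direction t per dataset.  Every pair's
criteria vector is t plus noise.  Eligible pairs' EHR vectors are the
normalized mix s·t + (1−s)·g (g an idiosyncratic unit direction) plus
noise; ineligible EHR vectors are g plus noise.  The label is therefore
carried by the EHR–criteria *correlation through the latent direction*,
not by surface equality of the two vectors — eligible pairs are never
near-duplicates.  At s = 0 the two classes are distributionally identical,
giving an exact null for leakage checks; macro-F1 there must sit at chance
(≤ 0.5 in expectation for any label-independent classifier).  Fine mode
scatters per-token rows around the same document centroids.  Structured
mode constructs records whose noiseless label is exactly "all inclusion
predicates hold and no exclusion predicate does", then flips labels at the
configured noise rate; impossible rule sets (empty eligible region) raise
a generation error after bounded retries.

What the synthetic beds do *not* emulate: real clinical language, LM
semantic geometry, correlated/structured noise, multi-trial heterogeneity,
or label ambiguity.  Passing tests therefore demonstrate that the
machinery (embedding plumbing, shared-weight training, imbalance handling,
fold hygiene, metrics) is correct and that the architecture can exploit a
latent semantic coupling — not that any particular F1 would transfer to
hospital data.

## Numerical and design choices

* float64 throughout; gradient correctness is tested against central
  finite differences for every encoder family.
* Probability threshold 0.5 with ties resolving to the positive class
  (documented tie rule).
* The dropout-rate grid for the coarse analysis reads {0.1, 0.3, 0.5,
  0.8, 0.9}; 0.1 is the MLP default.
* PCA projections fix component signs (largest-magnitude loading
  positive) so repeated runs agree exactly; t-SNE is seeded, defaults to
  perplexity min(30, (n−1)/3), and when requested on wide matrices runs
  after a PCA reduction to 50 dimensions (each method is also available
  alone).
* Batch-norm running statistics are part of checkpoints, so a reloaded
  model reproduces eval-mode outputs bit-exactly.
* Problem sizes in the test suite and the acceptance script (cohorts of
  40–180 pairs, embedding dimensions 16–64) are the scales the package
  targets: single-trial cohorts on one CPU.

## Known limitations

* The hashed provider carries no semantics; results on it say nothing
  about which real LM layer/pooling works best.
* The contrastive inference rule (threshold at margin/2) is a design
  choice; the objective itself does not pin down a decision rule.
* Macro-F1 on 36-sample folds is quantized (one flipped prediction moves
  it by a few points), so comparisons at small k are coarse.
* The paired t-test on five folds violates independence assumptions
  mildly; it is reported as an indicative, not confirmatory, statistic.
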