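# Methods

## The prediction problem

Compound-protein interaction (CPI) prediction is cast as proteochemometrics:
one binary classifier over *pairs* (compound, protein), so a single model
can extrapolate to both new compounds and new targets.  The model family is
the pairwise-input neural network (PINN): each input side passes through
its own stack of *separated* dense layers (no cross-connections), the
per-channel representations are concatenated, and a *concatenated* dense
stack feeds one sigmoid output.  The multi-channel variant (MCPINN)
attaches several feature channels per side and merges them all at the
concatenated layer.

Because each channel enters the merge with the width of its last separated
layer, channels of very different raw dimensionality (a 1024-bit
fingerprint vs. a 300-dim embedding) contribute comparably.  The same
structure is why a PINN needs roughly half the parameters of a plain
feed-forward network on the concatenated input with the same layer widths
(`model.feed_forward_parameter_count` reconstructs that baseline; the toy
and full-width counts are asserted in the test suite).

## Feature channels

Per side, three kinds of channels are available:

* **One-hot sequence channels** (`encoding`): character-level tokenization
  of SMILES (case-sensitive) and amino-acid sequences (upper-cased),
  one-hot encoded at fixed length — 100 for SMILES, 700 for proteins at
  full scale (the desk-scale default for proteins is 150) — truncating
  from the end and zero-padding at the end.  Padding is the all-zero row;
  in index form the pad index maps to a frozen zero embedding row, so both
  forms are equivalent model inputs.  The vocabulary is the sorted set of
  characters in the corpus (train+test by default; a train-only mode
  simply means passing a different corpus to `build_vocabulary`).
* **Fingerprint channel**: 1024-bit ECFP4 (Morgan radius 2) via RDKit.
* **Embedding channels** (`embedding`): molecules and proteins as
  sentences of words — Morgan substructure identifiers (radii {0, 1}) for
  compounds, shifted non-overlapping 3-grams for proteins (every length-3
  window appears exactly once across the n shifted readings).  Words are
  embedded by skip-gram with negative sampling (implemented in NumPy,
  trained in-process; full-scale reference hyperparameters d = 300,
  window = 35, min-count = 2; desk-scale runs default to d = 96).  A
  sentence is aggregated to one vector by sum, arithmetic mean, or TF-IDF
  weighted sum.  The TF-IDF weight uses the smoothed idf
  ln((1 + n_docs)/(1 + df)) + 1 with raw term counts, no norm; a
  `normalize` flag divides by the total weight for the "weighted average"
  reading of the operator.  Out-of-vocabulary words default to the zero
  vector (the behaviour used when an entity has no sequence at all).

## Architecture and training defaults

Defaults follow the reference protocol: ELU (alpha 1.0), Lecun-uniform
initialization (+-sqrt(3/fan_in)), dropout 10% on the channel inputs and
50% on hidden dense layers, separated widths 1024/256 with two separated
layers for single-channel and one for multi-channel models, one
concatenated layer of 256, a single sigmoid output; Adam (lr 5e-4, beta1
0.9, beta2 0.999), mini-batch 1024 at full scale, class-weighted binary
cross-entropy with w_pos = n_neg/n_pos, and per-update learning-rate decay
lr_t = lr/(1 + 1e-5 * t) (the "weight decay reduces the learning rate over
each update" reading; an L2 option exists for comparison).  Early stopping
monitors validation MCC with patience 20 by default.  The epoch budget is
400 for cross-validation runs and 500 for final training; desk-scale runs
use 50.

The dilated-CNN channel uses a 16-dim token embedding, 16 filters, kernel
12, valid padding, and a dilation schedule chosen so the receptive field
1 + (k-1) * sum(dilations) fits the fixed length: [1, 2, 4] for length 100
(field 78) and [1, 2, 4, 8] for length 700 (field 166).  Sequence-to-vector
reduction is global max pooling (padding rows are all-zero and never win
the max).  No residual connections are used.  LSTM/BLSTM channels use 256
units at full scale with forget bias 1.0 and consume the one-hot sequence
directly, emitting the final state (BLSTM concatenates both directions);
no padding mask is applied, matching the plain recurrent baseline.

High-level (dense) channel features are standardized to zero mean and unit
variance with statistics from the training split only; zero-variance
features map to 0.

All of this runs on a NumPy forward/backward kernel written for this
package (`mcpinn.nn`): no deep-learning framework is required, training is
single-threaded and bit-deterministic for a fixed seed, and freezing a
parameter group is exact (frozen tensors receive no optimizer update at
all).

## Evaluation and ranking

MCC (threshold 0.5; zero-denominator convention -> 0), ROC AUC and PRC AUC
(step-wise average precision, no interpolation) — the latter two delegated
to scikit-learn and cross-checked in the tests against an exhaustive
pairwise-concordance oracle and a hand step-rule.  Model ranking
standardizes each metric across models within every (replicate, metric)
slice (population sd; a pooled option exists), averages z-scores over
metrics and replicates, and tests pairwise differences with the paired
Student t test and a two-sided variance-ratio F test (the classical
two-sample variance comparison; degenerate comparisons report p = 1).
Convergence readouts: initial performance is the validation metric at
epoch 1; the convergence epoch is the first epoch reaching a stated
fraction (98%, or 95% for transfer runs) of the trajectory's best.
Convergence is reported in epochs; wall-clock is recorded per epoch but is
hardware-bound and not a test target.

## Transfer protocol

Pretraining runs 140 epochs on the source task with a checkpoint every 5
epochs (PM_0 is the untrained initialization, saved before any update;
optimizer state is checkpointed too, so training can resume
deterministically).  Each PM_i is finetuned on the target task (budget 200
epochs with early stopping) under one of four strategies; the small-and-
dissimilar scenario freezes every group below the concatenated stack and
re-initializes the concatenated stack and output ("top layers" =
concatenated + output; each finetune starts a fresh optimizer).  Whether
the executed choice is full-network finetuning (scenario 1) or scenario
4's freezing is left to the caller — both are one flag apart.  Checkpoints
are compared on initial performance, epochs to 95% of best, and highest
metric, with paired t tests against PM_0.

## Synthetic data generator

The generator emulates the two data regimes of the full-scale study — a
balanced bioactivity task (54.7% positives) and a strongly imbalanced
toxicity task (7.49% positives) — at desk scale: 2,000 compounds x 200
proteins x 20,000 sampled pairs by default, SMILES length 75th percentile
63, protein length 75th percentile 120 (scaled down from 712).

*Compounds* are assembled from a fragment grammar (alkyl chain atoms,
benzene/cyclohexane/pyridine rings, carbonyl/amide/ether/amine branches)
whose concatenations are valid SMILES; every string is verified with
RDKit.  *Proteins* are drawn from 10 compositional families — archetype
amino-acid usages drawn from a low-concentration Dirichlet so the
families are far apart, with tight within-family variation — echoing how
real target sets cluster into families with distinct sequence statistics;
lengths are log-normal.  The wide family separation is deliberate: the
recoverable protein-side signal of an aggregated N-gram embedding is
dominated by family identity, and between-family variance must dominate
the multinomial sampling noise of any single realized sequence.

*Labels* come from a latent rule with main effects and an interaction:

    P(y=1) = sigmoid( scale * [ sqrt(w) z_inter + sqrt(1-w) z_main ] + b + eps )

where z_inter standardizes the bilinear term <u_c, v_p> and z_main
standardizes (main_c + main_p) over the sampled pairs, w = 0.3 is the
interaction weight (main effects dominate, as they do in real bioactivity
matrices: compound promiscuity and target stickiness), eps ~ N(0,
noise_sd) with noise_sd = 0.25 by default, and `scale` sets the latent
logit sd to 7 so labels are fairly but not perfectly deterministic.  The
latent quantities are seeded random projections of *observable*
composition: the compound side loads sparsely on 64 of the 1024 standard
ECFP4 bits — restricted to bits whose presence frequency in the generated
library lies in 5-60%, since a pharmacophore absent from or ubiquitous in
a library cannot shape its activity pattern — and the protein side on the
20-dim amino-acid composition.  The sparse, frequency-filtered loading
makes the compound signal exactly linear in the fingerprint channel a
model sees and keeps it concentrated on learnable, commonly varying bits.
The intercept b is bisected until the realized positive rate matches the
target within +-0.5 percentage points (the label draws are fixed during
bisection, so calibration is exact and deterministic).

Because the signal is a function of observable features, learnability
tests are meaningful: the information ceiling of a feature pair can be
audited with the shipped ground truth (latent vectors, scale, intercept
are written to the truth file).  What the generator does **not** emulate:
chemically realistic bioactivity, target-class composition, assay noise
structure, train/test distribution shift, or any sequence-order signal
beyond composition — so a passing end-to-end test shows the pipeline
learns a recoverable pair signal at this scale, not that it matches
full-scale benchmark performance.

For related-task experiments, `generate_task_pair(spec, similarity)`
blends the source rule with an independent one (weights s and
sqrt(1 - s^2), preserving norms): similarity 1 reuses the rule exactly,
0 gives an uncorrelated one, and the latent logit correlation increases
monotonically in between.  The target task defaults to the imbalanced
positive rate.

## Desk-scale problem sizes

The package's own experiment defaults (RunConfig) are sized for a single
CPU: separated widths [256, 64], concatenated [64], batch 128, 50 epochs,
embedding d = 96 trained 6 epochs on the dataset's own sentences, protein
fixed length 150.  The acceptance script and test suite use these sizes;
the full-scale defaults remain available through the dataclasses.

## Numerical choices and edge cases

* MCC returns 0 when any confusion marginal is empty.
* ROC AUC requires both classes; PRC AUC requires at least one positive.
* The z-score ranking raises on a zero-variance (replicate, metric) slice
  rather than emitting infinities.
* Sequences longer than the fixed length are truncated from the end;
  unknown characters raise with the offending character and position.
* Dropout is inverted (scaling at train time), so evaluation is a plain
  forward pass.
* The skip-gram trainer uses a dynamic window (uniform 1..window per
  token), unigram^0.75 negative sampling, chunked (512-pair) updates with
  a linearly decaying step and elementwise step clipping — one big batched
  update at the full rate can compound repeated hits on a frequent word
  into divergence; determinism follows from the single seeded generator.

## Known limitations

* The NumPy kernel is single-threaded; full-scale (1024-batch, 500-epoch,
  700-length) runs are out of desk reach — the architecture supports them,
  the wall-clock does not.
* LSTM/BLSTM channels are implemented and gradient-checked but are slow in
  pure NumPy; the dilated CNN is the practical end-to-end channel at desk
  scale, mirroring the reference protocol's own preference.
* Skip-gram embeddings trained on 200-protein corpora are noisy; the
  protein channel's recoverable information is correspondingly the family
  structure plus a partial composition signal, not exact composition.
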