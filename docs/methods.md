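# Methods

This note documents the models and procedures `stslens` implements, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic-data validation does and does not establish.

## Item model

The unit of analysis is a scored sentence pair: two token sequences and a
gold similarity score in [0, 5]. Corpora carry a train/test split; the
train split supplies the token-frequency vocabulary used by the feature
analysis. Pairs are capped at 125 tokens across both sentences, leaving
room for three special tokens ([CLS] plus two [SEP]) within a 128-token
encoder window. Two input layouts are supported: `cls_first`
(`[CLS] A [SEP] B [SEP]`, BERT-style) and `cls_last`
(`A [SEP] B [SEP] [CLS]`, XLNet-style).

## Synthetic data generator

The generator emulates the statistical shape of expert-scored clinical STS
corpora, not their language. Defaults are the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_train / n_test | 1642 / 412 | corpus scale |
| score_levels | 0.0, 0.5, …, 5.0 | half-point gold labels |
| vocab_size | 2000 | content token types |
| zipf_exponent | 1.1 | frequency skew of content tokens |
| stopword_rate | 0.2 | per-position chance of a stop word (25-word built-in list, v1) |
| sentence length | 6–18 tokens | uniform per sentence |
| overlap_coupling | 0.7 | how strongly token overlap tracks the score |
| overlap_jitter | 0.15 | within-label spread of the copied-token fraction |

Overlap is planted by copying a fraction `coupling · score/5` (plus
Gaussian jitter, clipped to [0, 1]) of sentence A's tokens into sentence B.
The jitter matters: real corpora contain dissimilar pairs with heavy
lexical overlap and near-identical paraphrases with little, and the
error-analysis signatures below only exist when the generator reproduces
that within-label spread. At `overlap_coupling=1, overlap_jitter=0` a
score-5 pair shares its full token set and the Jaccard-distance/score
Spearman correlation is ≤ −0.9 by construction.

Predicted scores emulate an overlap-reliant model:

    prediction = clip(score + additive_bias
                      + strength · (overlap − mean overlap)
                      + N(0, noise_sd²), 0, 5)

with `overlap = 1 − Jaccard distance` centred on its test-split mean.
Clipping at the scale ends is what produces the per-label sign structure:
at label 0 only upward (over-prediction) errors survive, so loss grows
with overlap; at label 5 only downward errors survive, so loss grows as
overlap falls. The bias conditions used in the recovery tests are
strength 1.5, noise sd 0.25.

Activations are iid N(0, 1) token vectors per layer. Signal planting is
surgical: to plant into a pooled statistic, every token of the relevant
sentence is shifted by a constant vector, which commutes with both mean-
and max-pooling, so the target statistic is hit exactly:

* vector representations receive `strength · (score − mean score)` (plus
  optional coefficient noise) along a fixed random unit direction;
* the absolute-difference representations receive
  `(K + strength·(score − mean) + noise) · |u|` with the margin K sized so
  the coefficient stays positive, making the elementwise absolute value
  exactly linear in the score;
* the cosine-distance scalars place the pooled sentence-A vector on one
  axis and rotate pooled B by an angle `(π/2)(1 − score/5)`, so the
  distance is exactly monotone in dissimilarity.

A consequence worth knowing: an absolute-difference plant is
magnitude-coded along one fixed direction, so a *cosine* RDM built from
it carries almost no signal even though a linear probe decodes it
perfectly — direction-coded plants (e.g. [CLS]) are the right targets for
RSA recovery experiments. Plantings on the same layer are applied in
order and may interact; recovery experiments should use one per layer.

All randomness derives from one root integer seed through a counter-based
label-hashing scheme (`seeding.py`), so any stage can be re-run in
isolation and still draws the bits it would have drawn in the full
pipeline, and regenerated TSV/HDF5 outputs are byte-identical (HDF5
datasets are written with `track_times=False`).

## Surface features

`avg_sentence_length` is the *total* token count over both sentences —
the literal definition behind the conventional name; `halve_length=True`
divides by two. Frequency features count occurrences over both token
lists (duplicates included) after removing stop words, divided by the
total length; the unseen-token feature and the Jaccard distance use all
tokens, and Jaccard is computed on token sets. The correlation table
reports Spearman ρ (average ranks for ties) of loss against each feature,
overall and per label level; groups under 3 rows, or with constant loss
or feature, report a missing value rather than 0. The Bonferroni factor
is (number of features) × (number of evaluated groups) — 5 × 12 = 60 for
the default table.

## Linear probing

The probe is minimum-norm least squares with an intercept (column/target
centering followed by `lstsq`). Rationale: concatenated representations
reach twice the hidden size and exceed the item count, so normal
equations are singular; the pseudoinverse solution is deterministic and
adds no regularization hyperparameter. A ridge flag exists for
sensitivity analysis. Cross-validation shuffles items with a recorded
seed into 10 contiguous folds; the reported statistic is the Pearson
correlation between pooled out-of-fold predictions and the targets
(stabler at small n than fold-averaged correlations). Constant targets
or predictions report a missing value. `folds = n` reproduces
leave-one-out exactly. Layer selection: all layers for depth ≤ 12, even
layers for depth 24, otherwise an evenly spaced subset of at most 12.

## RSA

Ground truth is the absolute score-difference RDM. Vector
representations are compared by cosine distance, scalar representations
and text features by absolute difference; one RDM per scalar text
feature rather than a pooled feature RDM, so each feature can earn its
own weight in the recombination. All RDM comparisons use the
strictly-upper triangle with average-rank ties.

NNLS reweighting solves `min ‖Σ wᵢ·vec(Rᵢ) − vec(target)‖, w ≥ 0` with
scipy's NNLS after an exact Gram reduction (eigendecomposition of AᵀA;
identical optimum, much faster for 412-item designs with ~125
candidates). Cross-validation folds are defined over items: training
uses train×train triangle entries only, and the held-out evaluation uses
every triangle entry involving at least one held-out item — the
held-out×held-out block alone can be empty at small fold sizes. Reported
weights are fold averages normalized to sum to 1 (the Spearman objective
is scale-invariant, so normalization is presentation only); both the
held-out and the training Spearman are recorded. No constant/intercept
RDM is included by default (a flag could add one); with non-negative,
uncentered RDM designs this means a rank-anticorrelated candidate can
still receive positive weight by fitting the target's mean — only
candidates anti-aligned in the least-squares sense are forced to zero.

## Pipeline

Stages (`simulate`, `featurize`, `represent`, `probe`, `rsa`, `reweight`,
`report`) communicate exclusively through documented on-disk formats, so
any stage can be re-run or skipped when its inputs already exist. The
manifest records the config hash, per-stage derived seeds, package
version and SHA-256 checksums of all outputs; identical configs
reproduce identical checksums. Configs are strict YAML: unknown keys are
errors, because silent config drift is the main reproducibility hazard.
An adapter for dumping real transformer activations into the HDF5 layout
is a documented extension point (the format is fixed; no adapter is
shipped).

The default run uses two virtual models — 12 layers `cls_first` and
24 layers `cls_last`, hidden size 64 — with planted signals at known
cells, and five simulated prediction models with varied overlap bias
feeding a `mean_score` ensemble. Hidden size 64 is the package's default
problem size for end-to-end runs; the generator supports the full
768/1024 hidden sizes of real 12/24-layer encoders when more fidelity is
wanted.

## What the synthetic validation shows — and does not

Passing recovery tests establish that each analysis detects exactly the
structure it claims to measure (planted biases, planted layer-wise
signals, known convex combinations of RDMs) and nothing when no
structure is planted. They do not establish anything about real clinical
text: synthetic sentences are token sequences without syntax, subword
tokenization is not emulated, activations are Gaussian rather than
transformer-distributed, and planted signals are cleaner than any
learned representation. Conclusions about a real model still require
running the same pipeline on real activations via the HDF5 layout.

## Numerical notes

* Cosine distance raises on zero-norm pooled vectors rather than
  returning 0; with Gaussian activations this occurs with probability 0.
* `rank_top` breaks score ties lexicographically by
  (model, representation, layer) for deterministic output.
* NNLS residuals are reported as `‖Aw − b‖` computed directly, avoiding
  cancellation in the quadratic form.
* Probe correlations are invariant to positive affine transforms of the
  features; tests assert this at 1e−9.
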