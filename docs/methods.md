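# Methods

## Problem and model

`mgfdta` predicts the real-valued binding affinity of a drug–target pair
(pKd, KIBA score, or a transformed Kd) from the drug's SMILES string and
the protein's amino-acid sequence. The architecture fuses representations
at several granularities:

**Drug branch.** A (pluggable) chemical language model produces per-token
SMILES embeddings `c_smi`, linearly projected to the branch width `d_c` and
fine-tuned by a transformer encoder, then layer-normalized to give `f_s`.
Two molecular fingerprints — Morgan (radius 2, 2048 bits by default) and
Avalon (512 bits) — are each projected to `d_c` and fused with `f_s` by a
position-aware gated mechanism:

    Z  = concat[f_s, f_fp, f_s + f_fp]
    G  = σ(W_g Z + b)                    (per position, per feature)
    E  = (f_s ⊙ f_fp) / d,  d = √d_c
    A  = masked softmax of E over positions
    W_f = mean of A over valid positions
    f'_d = G ⊙ f_s + (1 − G) ⊙ f_fp ⊙ W_f

and the Morgan- and Avalon-fused streams are averaged into `f_d`. Because
each level of `A` is a softmax over positions, `W_f` reduces to the
reciprocal of the valid length; we keep the full computation so the fused
output is invariant to padding and the formulation stays faithful to the
gating design.

**Protein branch.** A (pluggable) protein language model yields per-residue
embeddings, projected to `d_t`, transformer-fine-tuned and normalized into
`f_p`. Language-model backbones cap the input length (the mock adapter
truncates at 1022 residues with a warning), so a second pathway summarizes
the *entire* sequence: sliding-window 3-mers are counted into
relative-frequency vectors over a capped vocabulary, Z-scored, and
PCA-projected; the reduced vector is reshaped into a pseudo-sequence of
chunks, transformer-encoded and attention-pooled into `f_mer`. A
per-position confidence derived from the squared norm of the normalized
residue features,

    W_esm = σ(‖x_pos‖² / D),

controls a residual injection `f_t = f_p + (1 − W_esm) · f_mer`: where the
language model is weak, the global composition signal contributes more. The
squared norm is used as such (no square root), and dividing by the feature
dimension `D` keeps the sigmoid in its responsive range for unit-variance
features; an all-zero position maps to exactly 0.5.

**Pooling and head.** Each branch is collapsed by hierarchical attention
pooling: `N` independent additive-attention levels
`S_i = W_i2 tanh(W_i1 X)`, masked softmax over positions, context
`C_i = Σ A_i X`, and the mean of the `N` contexts. `N = 3` by default with
hidden width `d_c/2`; with `N = 1` this is plain additive attention. The
pooled drug and protein vectors are concatenated and passed through a
fully connected head (hidden sizes 1024/512 at benchmark scale, ReLU,
dropout 0.1) to one prediction.

## k-mer featurization details

* Window `k = 3`, stride 1; a sequence shorter than `k` maps to the zero
  vector. Unknown characters are counted literally.
* The vocabulary keeps the `max_size` most frequent distinct 3-mers of the
  *training* corpus, counted per corpus; ties break by first occurrence, so
  the vocabulary is deterministic.
* Frequencies are divided by the sequence's total 3-mer count (in- or
  out-of-vocabulary), which removes sequence-length bias.
* Z-scoring uses the population standard deviation (the usual Z-score /
  `StandardScaler` convention); zero-variance features get σ = 1 so they
  standardize to exactly 0. The PCA covariance uses the sample (n−1)
  normalization, computed by SVD of the standardized matrix.
* Components are sign-fixed (largest-magnitude entry positive); the
  requested output dimension (1024 by default) is clamped to the data rank
  with a warning, and downstream consumers zero-pad to the configured
  dimension.
* Vocabulary, scaler and PCA are fitted on training sequences only and
  serialized together; a provenance tag is checked at feature-cache
  construction, so fitting on anything but the training split is an error,
  not a silent leak.

## Metrics

MSE, MAE, Pearson, Spearman, concordance index (CI) and rm² are computed
exactly as used in the affinity-prediction literature:

* CI counts ordered pairs with strictly greater true affinity; correct
  prediction order scores 1, a prediction tie 0.5, a reversal 0; true-value
  ties are excluded from the normalizer. An O(n log n) Fenwick-tree
  implementation is cross-checked against the O(n²) enumeration.
* Spearman uses mean ranks under ties then the Pearson of ranks; the
  classical 1 − 6Σd²/(n(n²−1)) shortcut is exact only without ties and is
  verified in that regime.
* rm² follows Roy's formula r²·(1 − √|r² − r0²|) with r² the squared
  correlation of the with-intercept fit and r0² the coefficient of
  determination of the through-origin fit of y on ŷ (the y-on-ŷ convention
  is recorded in the CLI report metadata).

## Training protocol

Adam (lr 1e-3 by default), MSE loss, `ReduceLROnPlateau`-style halving on
stalled validation MSE, best-validation checkpointing, and full seed
control of initialization, shuffling and dropout. Targets are standardized
with train-split mean/sd (inverted at prediction; the statistics travel in
the checkpoint). Batches are length-bucketed to limit padding. Datasets are
split 8:1:1 at the pair level; repeated cross-validation holds out a fresh
seeded 10 % test fraction per repeat and runs k-fold CV on the remainder,
refitting the k-mer transforms inside every fold. Benchmark-scale defaults
(epochs 500/500/300, batch 256/128/128 for kinase-sized datasets) live in
`ModelConfig`; the synthetic studies below use a deliberately small
configuration (`d_c = d_t = 32`, PCA dim 64, 8 chunks, 2 heads, head
64/32, batch 16, 30 epochs) so a full run takes about two minutes on one
CPU core.

## Synthetic data generator

`generate_fixture` emulates a small affinity benchmark: 10 drugs × 20
proteins (200 pairs) by default. Drugs are valid SMILES assembled from a
chain-extension grammar (verified against RDKit). Proteins (50–300
residues) are concatenations of 3-mers drawn from a protein-specific
8-element sub-pool of a 40-element shared pool. Every drug carries a
pseudo-motif of five 3-mers drawn from a common 8-element binding pool,
and the noise-free label is

    y = 5.0 + 12.0 · (fraction of the protein's 3-mers found in the motif's 3-mer set)

plus Gaussian noise (σ = 0.1 by default), giving a pKd-like scale.
Because all motifs share the binding pool, proteins rich in binding-pool
3-mers bind most drugs more strongly — a composition main effect (~57 % of
label variance) that a sequence-based model can recover on held-out pairs —
while motif differences add drug-specific interaction structure on top.

What the generator does *not* emulate: real chemical binding physics,
assay noise structure, scaffold redundancy among drugs, homology structure
among proteins, or cold-start (unseen drug/protein) evaluation. Passing
the end-to-end test therefore shows that the architecture, masking,
featurization and optimization are wired correctly and can extract a
planted sequence signal — not that the model reaches benchmark accuracy on
real data.

## Numerical and design choices

* Masked softmax adds −1e9 to padded scores and multiplies the
  exponentials by the mask, so padded positions get exactly zero weight.
* All trainable computation runs on an in-package reverse-mode autodiff
  engine over float64 numpy arrays; gradients are verified against central
  finite differences.
* The fingerprint-to-token alignment broadcasts one projected
  molecule-level vector to every valid position; the pooled k-mer vector is
  likewise projected and broadcast before residual fusion.
* Mock embedders hash (token, position, seed) to fixed unit-variance
  vectors, so every test runs offline and deterministically across
  platforms; checkpoint-based language-model backends plug in through the
  same contract.
* The baseline for the end-to-end learning check is the constant
  train-mean predictor evaluated on test — the strongest label-blind
  constant. The variance of a 20-pair test split is the error of an oracle
  constant that already knows the test labels and is reported alongside,
  not used as the bar.
* Duplicate-pair resolution in the BindingDB-style preprocessor keeps the
  higher raw affinity before the 9 − log10(affinity in nM) transform;
  filters apply in the documented order and the pipeline is idempotent.

## Known limitations

* The autodiff engine is single-threaded numpy; benchmark-scale training
  (hundreds of epochs on 30k+ pairs) is out of reach — the defaults
  document the protocol rather than promise desk-scale reproduction.
* Checkpoint embedder backends (chemical BERT, ESM-family) are contracts,
  not bundled weights.
* The k-mer pathway uses `k = 3` only; gapped k-mers and reduced alphabets
  are out of scope.
* Cold-drug / cold-target splitting is available in spirit (splits are
  pair-level by design, matching the evaluated protocol) but not a default.
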