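# mgfdta

Multi-granularity fusion model for **drug–target binding affinity (DTA)
regression**: given a drug as a SMILES string and a protein as an
amino-acid sequence, predict a real-valued binding affinity (pKd, KIBA
score, or a transformed Kd). The package is aimed at computational
chemists and ML researchers who want a tested, CPU-runnable reference
implementation of the fusion architecture, its featurizers, and the
evaluation protocol used in the DTA literature.

## The model

Two branches produce fixed-length representations that a fully connected
head maps to one number, `ŷ = FC(concat(F_d, F_t))`:

* **Drug branch** — language-model token embeddings `f_s` (projected and
  transformer-fine-tuned) are fused with Morgan and Avalon fingerprints by
  a position-aware gate: `Z = concat[f_s, f_fp, f_s+f_fp]`,
  `G = σ(W_g Z + b)`, attention weights from `E = (f_s ⊙ f_fp)/√d_c`, and
  `f'_d = G⊙f_s + (1−G)⊙f_fp⊙W_f`; the two fingerprint streams are
  averaged.
* **Protein branch** — per-residue language-model features `f_p` are
  combined with a full-sequence 3-mer pathway (sliding-window 3-mer
  frequencies → capped vocabulary → Z-score → PCA → transformer +
  attention pooling → `f_mer`) through a confidence-weighted residual:
  `f_t = f_p + (1 − σ(‖x‖²/D))·f_mer`. The 3-mer pathway covers what the
  length-capped language model cannot.
* **Hierarchical attention pooling** — N independent additive-attention
  levels `S_i = W_i2 tanh(W_i1 X)` with masked softmax over positions;
  the N context vectors are averaged. The per-residue weights are
  exportable for interpretability.

Evaluation implements the six standard DTA metrics — MSE, MAE, Pearson,
Spearman, concordance index (with exact tie handling and an O(n log n)
implementation verified against brute force), and Roy's
rm² = r²(1 − √|r² − r0²|).

Everything trainable runs on an in-package reverse-mode autodiff engine
over numpy, so the whole pipeline — including tests — works on one CPU
with no deep-learning framework. Pre-trained embedder checkpoints are
optional backends behind a small contract; deterministic mock embedders
make every run reproducible offline. See `docs/methods.md` for the full
model account.

## Worked example

Train on a small synthetic benchmark with a planted sequence signal and
evaluate on the held-out test split:

```python
import mgfdta as m
from mgfdta.model import ModelConfig

config = ModelConfig(dc=32, dt=32, drug_embed_dim=32, protein_embed_dim=32,
                     morgan_bits=512, avalon_bits=256, pca_dim=64,
                     kmer_chunks=8, kmer_vocab_size=512, head_dims=(64, 32),
                     batch_size=16, encoder_heads=2, epochs=30, seed=1)
dataset = m.split(m.generate_fixture(seed=1, noise_sd=0.1), seed=1)
trained = m.train(dataset, config)
report = m.evaluate(trained, dataset.subset("test"))
print(report)
```

```
MetricsReport(mse=0.1054465212324919, mae=0.24138129725383917,
              pearson=0.5157112009228003, spearman=0.6210526315789473,
              ci=0.7315789473684211, rm2=0.1511752128901764, n=20)
```

The test MSE (0.105) is well below the constant mean-predictor baseline
(0.170 on this split): the model recovered a real part of the planted
3-mer-overlap signal from sequences alone. CI 0.73 means 73 % of
affinity-ordered test pairs are ranked correctly.

The k-mer featurizer alone, on a three-sequence corpus:

```python
vocab = m.build_vocabulary(["MATSK", "MATTE", "CATSE"], k=3, max_size=7)
print(vocab.kmers)        # ('MAT', 'ATS', 'TSK', 'ATT', 'TTE', 'CAT', 'TSE')
print(m.frequency_vector("MATSK", vocab).round(3))
# [0.333 0.333 0.333 0.    0.    0.    0.   ]
```

A CLI mirrors the library (`mgfdta featurize-proteins`, `featurize-drugs`,
`train`, `evaluate`, `predict`, `metrics`, `export-attention`); run
`mgfdta --help`.

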