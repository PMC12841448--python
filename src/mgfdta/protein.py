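"""Protein representation: residue language-model features combined with
full-sequence k-mer/PCA features by confidence-weighted residual fusion.

The language-model branch gives per-residue features f_p but inherits the
backbone's input-length cap; the k-mer branch summarizes the *entire*
sequence in one vector. The k-mer vector is reshaped into a short
pseudo-sequence of chunks, passed through a transformer encoder and
attention-pooled to f_mer. A per-position confidence

    W_esm = sigmoid( ||x_pos||^2 / D )

derived from the squared norm of the (normalized) residue features decides
how much of the k-mer signal is injected:

    f_t = f_p + (1 - W_esm) . f_mer

so positions where the language model is weak receive more of the global
composition signal.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._autodiff import Tensor
from .containers import TokenFeatureMatrix
from .errors import ConfigurationError
from .nn import Linear, Module, TransformerEncoderLayer, masked_softmax

__all__ = ["KmerPooler", "esm_confidence", "residual_fuse", "ResidualFusion"]


class KmerPooler(Module):
    """Transformer-encode the reduced k-mer vector and attention-pool it.

    The ``pca_dim``-length vector is split into ``n_chunks`` equal chunks
    (right-padded with zeros when not divisible, with a warning); each chunk
    is linearly mapped to ``hidden`` features, encoded, and the chunk axis
    is collapsed by additive attention whose weights sum to one.
    """

    def __init__(self, pca_dim: int, hidden: int, rng: np.random.Generator,
                 n_chunks: int = 16, n_heads: int = 4, dropout: float = 0.1):
        if n_chunks < 1:
            raise ConfigurationError("n_chunks must be >= 1")
        self.n_chunks = n_chunks
        self.pca_dim = pca_dim
        self.chunk_size = -(-pca_dim // n_chunks)  # ceil
        if pca_dim % n_chunks:
            warnings.warn(
                f"pca_dim {pca_dim} not divisible by {n_chunks} chunks; "
                f"right-padding to {self.chunk_size * n_chunks}", stacklevel=2)
        self.chunk_proj = Linear(self.chunk_size, hidden, rng)
        self.encoder = TransformerEncoderLayer(hidden, n_heads, 2 * hidden, rng,
                                               dropout=dropout)
        self.attn_proj = Linear(hidden, hidden, rng)
        self.attn_score = Linear(hidden, 1, rng)

    def __call__(self, emer: Tensor | np.ndarray) -> Tensor:
        x = emer if isinstance(emer, Tensor) else Tensor(np.asarray(emer, float))
        B, P = x.shape
        if P != self.pca_dim:
            raise ConfigurationError(f"expected {self.pca_dim}-dim input, got {P}")
        total = self.chunk_size * self.n_chunks
        if total != P:
            pad = Tensor(np.zeros((B, total - P)))
            from ._autodiff import concat
            x = concat([x, pad], axis=-1)
        chunks = x.reshape(B, self.n_chunks, self.chunk_size)
        h = self.chunk_proj(chunks)                       # (B, T, hidden)
        mask = np.ones((B, self.n_chunks))
        h = self.encoder(h, mask)
        scores = self.attn_score(self.attn_proj(h).tanh())  # (B, T, 1)
        weights = masked_softmax(scores, mask[..., None], axis=1)
        return (weights * h).sum(axis=1)                  # (B, hidden)


def esm_confidence(fp: TokenFeatureMatrix) -> Tensor:
    """Per-position confidence of the residue features, strictly in (0, 1).

    The squared feature norm is divided by the feature dimension before the
    sigmoid so that unit-variance features sit near the linear regime
    instead of saturating. An all-zero position maps to exactly 0.5.
    """
    x = fp.tensor()
    d = x.shape[-1]
    return ((x ** 2).sum(axis=-1, keepdims=True) / d).sigmoid()  # (B, L, 1)


class ResidualFusion(Module):
    """Projects the pooled k-mer vector to the residue feature dim."""

    def __init__(self, kmer_dim: int, residue_dim: int, rng: np.random.Generator):
        self.proj = Linear(kmer_dim, residue_dim, rng)


def residual_fuse(fp: TokenFeatureMatrix, fmer: Tensor,
                  wesm: Tensor, params: ResidualFusion) -> TokenFeatureMatrix:
    """f_t = f_p + (1 - W_esm) . f_mer, broadcast across valid positions."""
    x = fp.tensor()
    B, L, D = x.shape
    if fmer.ndim != 2 or fmer.shape[0] != B:
        raise ConfigurationError(f"fmer shape {fmer.shape} incompatible with batch {B}")
    if fmer.shape[1] != params.proj.weight.shape[0]:
        raise ConfigurationError("fmer dim does not match projection input")
    if wesm.shape != (B, L, 1):
        raise ConfigurationError(f"wesm shape {wesm.shape} != {(B, L, 1)}")
    mcol = Tensor(fp.mask[..., None])
    fmer_tok = params.proj(fmer).reshape(B, 1, D) * mcol
    ft = x + (1.0 - wesm) * fmer_tok
    return TokenFeatureMatrix(values=ft * mcol, mask=fp.mask)
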