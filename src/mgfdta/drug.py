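"""Drug representation: language-model token features fused with
molecular fingerprints by a position-aware gated mechanism.

For one fingerprint stream the fusion is

    Z  = concat[f_s, f_fp, f_s + f_fp]          (feature axis)
    G  = sigmoid(W_g Z + b)                      per position, per feature
    E  = (f_s .* f_fp) / d                       d = sqrt(d_c)
    A  = masked softmax of E over positions
    W_f = mean of A over valid positions         per-feature weight vector
    out = G .* f_s + (1 - G) .* f_fp .* W_f

where ``f_fp`` is the fingerprint linearly projected to the token feature
dimension and broadcast to every valid position. The Morgan- and
Avalon-fused streams are averaged to give the final drug feature f_d.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor, concat
from .containers import TokenFeatureMatrix
from .errors import ConfigurationError
from .nn import Linear, Module, masked_softmax

__all__ = ["GatedFusion", "gated_fuse", "fuse_drug"]


class GatedFusion(Module):
    """Learnable parameters of one gated fingerprint-fusion stream."""

    def __init__(self, feature_dim: int, fp_bits: int, rng: np.random.Generator,
                 scale: float | None = None):
        self.feature_dim = feature_dim
        self.fp_projection = Linear(fp_bits, feature_dim, rng)
        self.gate = Linear(3 * feature_dim, feature_dim, rng)
        self.scale = float(scale) if scale is not None else math.sqrt(feature_dim)
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")

    def project_fingerprint(self, fp_bits: Tensor | np.ndarray) -> Tensor:
        fp = fp_bits if isinstance(fp_bits, Tensor) else Tensor(np.asarray(fp_bits, float))
        if fp.shape[-1] != self.fp_projection.weight.shape[0]:
            raise ConfigurationError(
                f"fingerprint length {fp.shape[-1]} does not match projection "
                f"input {self.fp_projection.weight.shape[0]}")
        return self.fp_projection(fp)


def gated_fuse(fs: TokenFeatureMatrix, fp_bits: Tensor | np.ndarray,
               params: GatedFusion) -> TokenFeatureMatrix:
    """Fuse token features with one fingerprint stream (see module docstring).

    ``fp_bits`` is one fingerprint per batch element, shape (batch, nbits).
    Padded positions of the output are exactly zero, and the result does not
    depend on how much padding the batch carries.
    """
    x = fs.tensor()
    B, L, D = x.shape
    if D != params.feature_dim:
        raise ConfigurationError(f"token feature dim {D} != params dim {params.feature_dim}")
    mask = fs.mask  # (B, L)
    mcol = Tensor(mask[..., None])

    fp = params.project_fingerprint(fp_bits)              # (B, dc)
    fp_tok = fp.reshape(B, 1, D) * mcol                   # broadcast to valid positions

    z = concat([x, fp_tok, x + fp_tok], axis=-1)          # (B, L, 3dc)
    gate = params.gate(z).sigmoid()                       # (B, L, dc)

    e = x * fp_tok / params.scale                          # (B, L, dc)
    attn = masked_softmax(e, mask[..., None], axis=1)      # over positions
    n_valid = mask.sum(axis=1).reshape(B, 1, 1)
    wf = attn.sum(axis=1, keepdims=True) / Tensor(n_valid)  # (B, 1, dc)

    fused = gate * x + (1.0 - gate) * fp_tok * wf
    return TokenFeatureMatrix(values=fused * mcol, mask=mask)


def fuse_drug(fs: TokenFeatureMatrix, fmor_bits, fava_bits,
              params_mor: GatedFusion, params_ava: GatedFusion) -> TokenFeatureMatrix:
    """Average of the Morgan-fused and Avalon-fused streams: the final f_d."""
    a = gated_fuse(fs, fmor_bits, params_mor)
    b = gated_fuse(fs, fava_bits, params_ava)
    return TokenFeatureMatrix(values=(a.tensor() + b.tensor()) / 2.0, mask=fs.mask)
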