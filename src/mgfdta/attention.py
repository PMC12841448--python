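"""Hierarchical attention pooling.

Collapses a masked token feature matrix to one vector. Each of N levels is
an independent additive-attention head:

    S_i = W_i2 tanh(W_i1 X)        per-position score
    A_i = masked softmax of S_i    weights: >= 0, sum to 1 over valid positions
    C_i = sum_pos A_i X            context vector (convex combination)

and the pooled output is the mean of the N context vectors. With N = 1 this
reduces to standard additive attention pooling. The per-level weights are
exposed for interpretability (residue-level ranking).
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor
from .containers import TokenFeatureMatrix
from .errors import ConfigurationError, DegenerateInputError
from .nn import Linear, Module, masked_softmax

__all__ = ["AttentionLevel", "HierarchicalAttention",
           "attention_scores", "masked_normalize", "top_residues"]


class AttentionLevel(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.proj1 = Linear(dim, hidden, rng)
        self.proj2 = Linear(hidden, 1, rng)


def attention_scores(x: TokenFeatureMatrix, level: AttentionLevel) -> Tensor:
    """Raw per-position scores S = W2 tanh(W1 X), shape (batch, positions, 1)."""
    t = x.tensor()
    if t.shape[-1] != level.proj1.weight.shape[0]:
        raise ConfigurationError("feature dim does not match attention level")
    return level.proj2(level.proj1(t).tanh())


def masked_normalize(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over positions with padding excluded (exact zeros)."""
    mask = np.asarray(mask, dtype=np.float64)
    if np.any(mask.sum(axis=-1) < 1):
        raise DegenerateInputError("all positions masked")
    return masked_softmax(scores, mask[..., None], axis=1)


class HierarchicalAttention(Module):
    """N independent attention levels whose contexts are averaged."""

    def __init__(self, dim: int, rng: np.random.Generator, n_levels: int = 3,
                 hidden: int | None = None):
        if n_levels < 1:
            raise ConfigurationError("n_levels must be >= 1")
        hidden = hidden or max(dim // 2, 1)
        self.levels = [AttentionLevel(dim, hidden, rng) for _ in range(n_levels)]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_weights(self, x: TokenFeatureMatrix) -> list[Tensor]:
        """Per-level attention weights, each (batch, positions, 1)."""
        return [masked_normalize(attention_scores(x, lv), x.mask)
                for lv in self.levels]

    def __call__(self, x: TokenFeatureMatrix) -> Tensor:
        t = x.tensor()
        contexts = [(w * t).sum(axis=1) for w in self.level_weights(x)]
        out = contexts[0]
        for c in contexts[1:]:
            out = out + c
        return out / float(self.n_levels)

    def export_weights(self, x: TokenFeatureMatrix) -> dict[str, np.ndarray]:
        """Mean-over-levels and per-level weights as numpy, (batch, positions).

        Padded positions carry weight exactly 0; each level sums to 1 per
        sequence over valid positions.
        """
        per_level = np.stack([w.data[..., 0] for w in self.level_weights(x)])
        return {"mean": per_level.mean(axis=0), "per_level": per_level}


def top_residues(weights: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Indices (0-based) of the k highest-weight valid positions.

    Ties are broken by position order, mirroring how predicted interaction
    sites are matched against a known count of reference sites.
    """
    weights = np.where(np.asarray(mask, bool), weights, -np.inf)
    order = np.lexsort((np.arange(weights.shape[-1]), -weights))
    return np.sort(order[:k])
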