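"""Shared in-memory containers for token-level features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .errors import DegenerateInputError

__all__ = ["TokenFeatureMatrix"]


@dataclass
class TokenFeatureMatrix:
    """Per-position features for a batch of sequences plus a validity mask.

    ``values`` is (batch, positions, feature_dim) — a numpy array for frozen
    embedder output or an autodiff :class:`Tensor` inside the model graph.
    ``mask`` is (batch, positions) with 1 marking real tokens/residues and 0
    padding; every row must contain at least one valid position. Padded
    positions are kept as zero vectors so masked reductions stay exact.
    """

    values: np.ndarray | Tensor
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.float64)
        arr = self.values.data if isinstance(self.values, Tensor) else self.values
        if arr.ndim != 3 or self.mask.shape != arr.shape[:2]:
            raise DegenerateInputError(
                f"values {arr.shape} and mask {self.mask.shape} are inconsistent")
        if np.any(self.mask.sum(axis=1) < 1):
            raise DegenerateInputError("a batch row has no valid positions")

    @property
    def feature_dim(self) -> int:
        arr = self.values.data if isinstance(self.values, Tensor) else self.values
        return arr.shape[2]

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)

    def tensor(self) -> Tensor:
        """Lift values into the autodiff graph (no-op if already lifted)."""
        return self.values if isinstance(self.values, Tensor) else Tensor(self.values)

    def numpy(self) -> np.ndarray:
        return self.values.data if isinstance(self.values, Tensor) else self.values
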