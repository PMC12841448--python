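"""Sequence embedder backends.

The model consumes pre-trained language-model embeddings for SMILES tokens
and protein residues through a narrow contract: an embedder exposes ``dim``
and ``embed(sequence) -> (length, dim) array`` and is deterministic. The
mock backends below satisfy the contract offline: each (token, position)
pair is hashed to a fixed unit-variance random vector, so two calls — or
two processes — always agree. Checkpoint-based backends (e.g. a chemical
BERT for SMILES, an ESM-family model for proteins) plug in through the same
contract when their weights are available.
"""

from __future__ import annotations

import hashlib
import logging
import re
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .containers import TokenFeatureMatrix
from .errors import EmptyInputError, ParseError

__all__ = [
    "SequenceEmbedder", "MockSmilesEmbedder", "MockProteinEmbedder",
    "tokenize_smiles", "pad_batch", "get_embedder",
]

logger = logging.getLogger(__name__)

# Multi-character organic-subset and bracket tokens first, then single chars.
_SMILES_TOKEN = re.compile(
    r"\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}"
    r"|[A-IK-PR-Za-ik-pr-z]|\d|[=#\$:~\-\+\(\)/\\\.@\*]"
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens.

    Raises :class:`ParseError` (carrying the offending string) when any
    character is not covered by the token grammar.
    """
    if not smiles:
        raise ParseError("empty SMILES string")
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _SMILES_TOKEN.match(smiles, pos)
        if m is None:
            raise ParseError(
                f"untokenizable SMILES {smiles!r} at position {pos} "
                f"({smiles[pos]!r})")
        tokens.append(m.group())
        pos = m.end()
    return tokens


@runtime_checkable
class SequenceEmbedder(Protocol):
    """Contract every embedder backend satisfies."""

    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray:  # (length, dim)
        ...


def _hash_vector(seed: int, token: str, position: int, dim: int) -> np.ndarray:
    key = f"{seed}|{token}|{position}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


class MockSmilesEmbedder:
    """Deterministic stand-in for a pre-trained SMILES language model."""

    def __init__(self, dim: int = 64, seed: int = 0):
        self.name = "mock"
        self.dim = dim
        self.seed = seed

    def embed(self, smiles: str) -> np.ndarray:
        tokens = tokenize_smiles(smiles)
        return np.vstack([_hash_vector(self.seed, t, i, self.dim)
                          for i, t in enumerate(tokens)])


class MockProteinEmbedder:
    """Deterministic stand-in for a pre-trained protein language model.

    Mirrors the length cap of transformer protein models: sequences longer
    than ``max_len`` residues are truncated with a logged warning — the
    k-mer pathway is what covers the truncated tail.
    """

    def __init__(self, dim: int = 64, seed: int = 0, max_len: int = 1022):
        self.name = "mock"
        self.dim = dim
        self.seed = seed
        self.max_len = max_len

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise EmptyInputError("empty protein sequence")
        if len(sequence) > self.max_len:
            logger.warning(
                "protein sequence of length %d truncated to backend limit %d",
                len(sequence), self.max_len)
            sequence = sequence[: self.max_len]
        return np.vstack([_hash_vector(self.seed, aa, i, self.dim)
                          for i, aa in enumerate(sequence)])


def pad_batch(matrices: Sequence[np.ndarray]) -> TokenFeatureMatrix:
    """Right-pad per-sequence embeddings to the batch maximum length."""
    if not matrices:
        raise EmptyInputError("empty batch")
    dim = matrices[0].shape[1]
    max_len = max(m.shape[0] for m in matrices)
    values = np.zeros((len(matrices), max_len, dim))
    mask = np.zeros((len(matrices), max_len))
    for i, m in enumerate(matrices):
        values[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return TokenFeatureMatrix(values=values, mask=mask)


def get_embedder(spec: str, kind: str, dim: int, seed: int = 0) -> SequenceEmbedder:
    """Resolve a backend config key (``mock`` or ``checkpoint:<name>``)."""
    if spec == "mock":
        if kind == "drug":
            return MockSmilesEmbedder(dim=dim, seed=seed)
        if kind == "protein":
            return MockProteinEmbedder(dim=dim, seed=seed)
        raise ValueError(f"unknown embedder kind {kind!r}")
    if spec.startswith("checkpoint:"):
        raise NotImplementedError(
            f"checkpoint backend {spec!r} requires pre-trained weights; "
            "provide an object satisfying the SequenceEmbedder contract")
    raise ValueError(f"unknown embedder backend {spec!r}")
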