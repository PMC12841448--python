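"""Molecular fingerprint generation.

Morgan (ECFP-style circular) and Avalon (substructure-enumeration)
fingerprints computed with RDKit when it is importable; otherwise a
deterministic hashed-substring fallback keeps the pipeline runnable, with
the backend recorded in the vector's metadata so results are attributable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .embedders import tokenize_smiles
from .errors import InvalidParameterError, ParseError

__all__ = ["FingerprintVector", "fingerprint"]

try:
    from rdkit import Chem, RDLogger
    from rdkit.Avalon import pyAvalonTools
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    _HAVE_RDKIT = True
except ImportError:  # pragma: no cover - exercised only without RDKit
    _HAVE_RDKIT = False

_KINDS = ("morgan", "avalon")


@dataclass(frozen=True)
class FingerprintVector:
    bits: np.ndarray  # binary, shape (nbits,)
    kind: str
    nbits: int
    backend: str

    def __post_init__(self):
        if self.bits.shape != (self.nbits,):
            raise InvalidParameterError("fingerprint length differs from nbits")
        if not np.isin(self.bits, (0, 1)).all():
            raise InvalidParameterError("fingerprint bits must be binary")


def _rdkit_fingerprint(smiles: str, kind: str, nbits: int, radius: int) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"RDKit could not parse SMILES {smiles!r}")
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
        bv = gen.GetFingerprint(mol)
    else:
        bv = pyAvalonTools.GetAvalonFP(mol, nBits=nbits)
    out = np.zeros(nbits, dtype=np.uint8)
    out[list(bv.GetOnBits())] = 1
    return out


def _hashed_fingerprint(smiles: str, kind: str, nbits: int, radius: int) -> np.ndarray:
    """Deterministic fallback: hash token n-grams (n <= radius+1) to bits."""
    tokens = tokenize_smiles(smiles)
    out = np.zeros(nbits, dtype=np.uint8)
    for n in range(1, radius + 2):
        for i in range(len(tokens) - n + 1):
            key = f"{kind}|{n}|{''.join(tokens[i:i + n])}".encode()
            h = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "little")
            out[h % nbits] = 1
    return out


def fingerprint(smiles: str, kind: str = "morgan", nbits: int = 2048,
                radius: int = 2) -> FingerprintVector:
    """Binary fingerprint of a molecule.

    Parameters follow common practice: Morgan radius 2 with 2048 bits,
    Avalon with 512 bits (the Avalon scheme enumerates a fixed substructure
    catalogue, so fewer bits suffice).
    """
    if kind not in _KINDS:
        raise InvalidParameterError(f"kind must be one of {_KINDS}, got {kind!r}")
    if nbits < 1 or radius < 0:
        raise InvalidParameterError("nbits must be >= 1 and radius >= 0")
    if not smiles:
        raise ParseError("empty SMILES string")
    if _HAVE_RDKIT:
        bits = _rdkit_fingerprint(smiles, kind, nbits, radius)
        backend = "rdkit"
    else:
        bits = _hashed_fingerprint(smiles, kind, nbits, radius)
        backend = "hashed-fallback"
    return FingerprintVector(bits=bits, kind=kind, nbits=nbits, backend=backend)
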