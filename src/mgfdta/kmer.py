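"""Fixed-length protein featurization from 3-mer composition.

Long protein sequences are turned into fixed-length vectors in four steps:

1. sliding-window k-mer extraction (window ``k``, stride 1);
2. relative-frequency vectors over a capped, corpus-derived vocabulary
   (dividing by the total k-mer count of each sequence removes the bias a
   raw count vector carries from sequence length);
3. per-feature Z-score standardization;
4. PCA projection onto the leading principal components.

The vocabulary, scaler and projector are fitted on training sequences only
and serialized together, so applying them to held-out proteins leaks no
statistics. This pathway complements transformer protein embedders whose
input length is capped: the k-mer vector always covers the full sequence.
"""

from __future__ import annotations

import io
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "KmerVocabulary", "ZScoreScaler", "PCAProjector",
    "extract_kmers", "build_vocabulary", "frequency_vector",
    "frequency_matrix", "fit_scaler", "apply_scaler", "fit_pca", "project",
    "ProteinKmerFeaturizer",
]

_ARCHIVE_VERSION = 1


def extract_kmers(sequence: str, k: int = 3) -> list[str]:
    """All length-``k`` windows of ``sequence`` at stride 1, in order.

    A sequence shorter than ``k`` yields an empty list. Unknown characters
    are kept literally: the vocabulary, not this function, decides what is
    retained.
    """
    if k < 1:
        raise InvalidParameterError(f"window length k must be >= 1, got {k}")
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered, capped vocabulary of k-mers.

    ``kmers`` holds the ``max_size`` most frequent distinct k-mers of the
    fitting corpus; ties are broken by first occurrence, which makes the
    ordering deterministic for a given corpus.
    """

    k: int
    kmers: tuple[str, ...]
    max_size: int
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError("k must be >= 1")
        if self.max_size < 1:
            raise InvalidParameterError("max_size must be >= 1")
        if len(self.kmers) > self.max_size:
            raise InvalidParameterError("vocabulary exceeds max_size")
        if any(len(m) != self.k for m in self.kmers):
            raise InvalidParameterError("all vocabulary entries must have length k")
        if len(set(self.kmers)) != len(self.kmers):
            raise InvalidParameterError("vocabulary entries must be unique")
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(self.kmers)})

    def __len__(self) -> int:
        return len(self.kmers)

    def index(self, kmer: str) -> int | None:
        return self._index.get(kmer)


def build_vocabulary(sequences: Iterable[str], k: int = 3,
                     max_size: int = 8000) -> KmerVocabulary:
    """Corpus-wide k-mer counting, keeping the ``max_size`` most frequent.

    Frequencies are counted per corpus (every occurrence counts, not mere
    presence per sequence). Ties are broken by first occurrence order.
    """
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(extract_kmers(seq, k))
    if not counts:
        raise EmptyInputError("no sequence of length >= k in the corpus")
    # Counter preserves insertion order, so sorting by -count alone is a
    # stable first-occurrence tie-break.
    ranked = sorted(counts, key=lambda m: -counts[m])
    return KmerVocabulary(k=k, kmers=tuple(ranked[:max_size]), max_size=max_size)


def frequency_vector(sequence: str, vocab: KmerVocabulary) -> np.ndarray:
    """Relative-frequency vector of ``sequence`` over ``vocab``.

    Each component is the count of that vocabulary k-mer divided by the
    *total* number of k-mers in the sequence, in- or out-of-vocabulary, so
    the vector sums to (in-vocabulary count)/(total count) <= 1. Sequences
    with no k-mers map to the zero vector.
    """
    out = np.zeros(len(vocab))
    fragments = extract_kmers(sequence, vocab.k)
    if not fragments:
        return out
    for frag in fragments:
        j = vocab.index(frag)
        if j is not None:
            out[j] += 1.0
    return out / len(fragments)


def frequency_matrix(sequences: Sequence[str], vocab: KmerVocabulary) -> np.ndarray:
    """Stack of :func:`frequency_vector` rows, one per sequence."""
    return np.vstack([frequency_vector(s, vocab) for s in sequences]) \
        if sequences else np.zeros((0, len(vocab)))


@dataclass(frozen=True)
class ZScoreScaler:
    means: np.ndarray
    stds: np.ndarray


def fit_scaler(matrix: np.ndarray) -> ZScoreScaler:
    """Per-feature mean/std on the fitting rows (population std, as in the
    usual Z-score / StandardScaler convention; the PCA covariance keeps its
    own n-1 normalization).

    Constant features get std 1 so their standardized value is exactly 0.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise EmptyInputError("scaler fit requires a non-empty 2-D matrix")
    means = matrix.mean(axis=0)
    if matrix.shape[0] < 2:
        warnings.warn("fitting a scaler on a single row; stds forced to 1",
                      stacklevel=2)
        stds = np.ones(matrix.shape[1])
    else:
        stds = matrix.std(axis=0)
        stds = np.where(stds <= 0.0, 1.0, stds)
    return ZScoreScaler(means=means, stds=stds)


def apply_scaler(matrix: np.ndarray, scaler: ZScoreScaler) -> np.ndarray:
    return (np.asarray(matrix, dtype=np.float64) - scaler.means) / scaler.stds


@dataclass(frozen=True)
class PCAProjector:
    """Top principal directions of the standardized training matrix.

    ``components`` has orthonormal columns (one per kept component); the
    eigenvalues are the variances of the projected training columns, sorted
    descending. Each component's sign is fixed so its largest-magnitude
    entry is positive, resolving the inherent sign ambiguity.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    out_dim: int


def fit_pca(standardized: np.ndarray, out_dim: int = 1024) -> PCAProjector:
    """Eigendecomposition of the sample covariance C = Z'Z/(n-1) via SVD."""
    Z = np.asarray(standardized, dtype=np.float64)
    if out_dim < 1:
        raise InvalidParameterError("out_dim must be >= 1")
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise EmptyInputError("PCA fit requires >= 2 rows")
    n, p = Z.shape
    rank_cap = min(n - 1, p)
    eff_dim = min(out_dim, rank_cap)
    if eff_dim < out_dim:
        warnings.warn(
            f"out_dim {out_dim} exceeds data rank bound {rank_cap}; "
            f"clamped to {eff_dim}", stacklevel=2)
    _, s, vt = scipy.linalg.svd(Z, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    components = vt[:eff_dim].T.copy()
    # sign convention: largest-magnitude entry of each component positive
    flip = np.sign(components[np.abs(components).argmax(axis=0),
                              np.arange(eff_dim)])
    flip = np.where(flip == 0, 1.0, flip)
    components *= flip
    return PCAProjector(components=components,
                        eigenvalues=eigenvalues[:eff_dim],
                        out_dim=eff_dim)


def project(standardized: np.ndarray, projector: PCAProjector) -> np.ndarray:
    return np.asarray(standardized, dtype=np.float64) @ projector.components


class ProteinKmerFeaturizer:
    """End-to-end fitted pipeline: vocabulary -> frequencies -> Z-score -> PCA.

    ``fit`` must only ever see training sequences; ``provenance`` records
    the fit so downstream training code can assert leak-freedom.
    """

    def __init__(self, k: int = 3, vocab_size: int = 8000, pca_dim: int = 1024):
        self.k = k
        self.vocab_size = vocab_size
        self.pca_dim = pca_dim
        self.vocab: KmerVocabulary | None = None
        self.scaler: ZScoreScaler | None = None
        self.projector: PCAProjector | None = None
        self.provenance: dict = {}

    @property
    def is_fitted(self) -> bool:
        return self.projector is not None

    def fit(self, sequences: Sequence[str], provenance: str = "train") -> "ProteinKmerFeaturizer":
        self.vocab = build_vocabulary(sequences, self.k, self.vocab_size)
        A = frequency_matrix(sequences, self.vocab)
        self.scaler = fit_scaler(A)
        Z = apply_scaler(A, self.scaler)
        self.projector = fit_pca(Z, self.pca_dim)
        self.provenance = {"fitted_on": provenance, "n_sequences": len(sequences)}
        return self

    def transform(self, sequences: Sequence[str]) -> np.ndarray:
        if not self.is_fitted:
            raise InvalidParameterError("featurizer is not fitted")
        A = frequency_matrix(sequences, self.vocab)
        return project(apply_scaler(A, self.scaler), self.projector)

    def fit_transform(self, sequences: Sequence[str],
                      provenance: str = "train") -> np.ndarray:
        return self.fit(sequences, provenance).transform(sequences)

    # -- serialization: one archive, JSON header + binary matrices ----------
    def save(self, path: str | Path) -> None:
        if not self.is_fitted:
            raise InvalidParameterError("cannot save an unfitted featurizer")
        header = {
            "version": _ARCHIVE_VERSION,
            "k": self.k,
            "vocab_size": self.vocab_size,
            "pca_dim": self.pca_dim,
            "kmers": list(self.vocab.kmers),
            "provenance": self.provenance,
        }
        np.savez(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            means=self.scaler.means, stds=self.scaler.stds,
            components=self.projector.components,
            eigenvalues=self.projector.eigenvalues,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProteinKmerFeaturizer":
        with np.load(path) as arc:
            header = json.loads(bytes(arc["header"]).decode())
            if header["version"] != _ARCHIVE_VERSION:
                raise InvalidParameterError(
                    f"unsupported featurizer archive version {header['version']}")
            obj = cls(k=header["k"], vocab_size=header["vocab_size"],
                      pca_dim=header["pca_dim"])
            obj.vocab = KmerVocabulary(k=header["k"],
                                       kmers=tuple(header["kmers"]),
                                       max_size=header["vocab_size"])
            obj.scaler = ZScoreScaler(means=arc["means"], stds=arc["stds"])
            obj.projector = PCAProjector(components=arc["components"],
                                         eigenvalues=arc["eigenvalues"],
                                         out_dim=arc["components"].shape[1])
            obj.provenance = header["provenance"]
        return obj
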