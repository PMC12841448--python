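"""Full affinity-regression network.

Two branches produce fixed-length representations that a fully connected
head maps to one real-valued affinity:

* drug branch — SMILES token embeddings, linearly projected and fine-tuned
  by a transformer encoder, fused with Morgan and Avalon fingerprints by
  gated fusion, then hierarchically attention-pooled;
* protein branch — residue embeddings, projected/fine-tuned the same way,
  combined with the pooled k-mer/PCA vector by confidence-weighted residual
  fusion, then hierarchically attention-pooled.

    y_pred = FC(concat(F_drug, F_protein))
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from ._autodiff import Tensor, concat
from .attention import HierarchicalAttention
from .containers import TokenFeatureMatrix
from .drug import GatedFusion, fuse_drug
from .errors import ConfigurationError
from .nn import LayerNorm, Linear, MLPHead, Module, TransformerEncoderLayer
from .protein import KmerPooler, ResidualFusion, esm_confidence, residual_fuse

__all__ = ["ModelConfig", "ModelInputs", "MGFDTAModel"]


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training run.

    The optimizer defaults (lr 1e-3, batch 256, 500 epochs) are the
    grid-search winners for kinase-scale benchmarks; small synthetic runs
    override ``epochs`` and ``batch_size``.
    """

    dc: int = 128                 # drug branch hidden dim
    dt: int = 128                 # protein branch hidden dim
    drug_embed_dim: int = 64      # embedder output dim (drug)
    protein_embed_dim: int = 64   # embedder output dim (protein)
    morgan_bits: int = 2048
    morgan_radius: int = 2
    avalon_bits: int = 512
    kmer_k: int = 3
    kmer_vocab_size: int = 8000
    pca_dim: int = 1024
    kmer_chunks: int = 16
    attention_levels: int = 3
    attention_hidden: int | None = None
    encoder_layers: int = 1
    encoder_heads: int = 4
    head_dims: tuple[int, ...] = (1024, 512)
    dropout: float = 0.1
    drug_backend: str = "mock"
    protein_backend: str = "mock"
    lr: float = 1e-3
    batch_size: int = 256
    epochs: int = 500
    seed: int = 0
    standardize_labels: bool = True  # z-score targets on train stats
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10

    def __post_init__(self):
        for name in ("dc", "dt", "drug_embed_dim", "protein_embed_dim",
                     "morgan_bits", "avalon_bits", "pca_dim", "kmer_chunks",
                     "attention_levels", "encoder_layers", "encoder_heads",
                     "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        self.head_dims = tuple(self.head_dims)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class ModelInputs:
    """One featurized, padded, masked batch."""

    drug_tokens: TokenFeatureMatrix           # (B, Ld, drug_embed_dim)
    morgan: np.ndarray                        # (B, morgan_bits)
    avalon: np.ndarray                        # (B, avalon_bits)
    protein_tokens: TokenFeatureMatrix        # (B, Lp, protein_embed_dim)
    kmer: np.ndarray                          # (B, pca_dim)

    def __post_init__(self):
        b = self.drug_tokens.mask.shape[0]
        for arr, name in ((self.morgan, "morgan"), (self.avalon, "avalon"),
                          (self.kmer, "kmer")):
            if arr.shape[0] != b:
                raise ConfigurationError(f"{name} batch size {arr.shape[0]} != {b}")
        if self.protein_tokens.mask.shape[0] != b:
            raise ConfigurationError("protein batch size mismatch")


class MGFDTAModel(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        # drug branch
        self.wd = Linear(c.drug_embed_dim, c.dc, rng)
        self.drug_encoder = [TransformerEncoderLayer(c.dc, c.encoder_heads,
                                                     2 * c.dc, rng, c.dropout)
                             for _ in range(c.encoder_layers)]
        self.drug_norm = LayerNorm(c.dc)
        self.fusion_morgan = GatedFusion(c.dc, c.morgan_bits, rng)
        self.fusion_avalon = GatedFusion(c.dc, c.avalon_bits, rng)
        self.drug_pool = HierarchicalAttention(c.dc, rng, c.attention_levels,
                                               c.attention_hidden)

        # protein branch
        self.wp = Linear(c.protein_embed_dim, c.dt, rng)
        self.protein_encoder = [TransformerEncoderLayer(c.dt, c.encoder_heads,
                                                        2 * c.dt, rng, c.dropout)
                                for _ in range(c.encoder_layers)]
        self.protein_norm = LayerNorm(c.dt)
        self.kmer_pooler = KmerPooler(c.pca_dim, c.dt, rng, c.kmer_chunks,
                                      c.encoder_heads, c.dropout)
        self.kmer_norm = LayerNorm(c.dt)
        self.residual_fusion = ResidualFusion(c.dt, c.dt, rng)
        self.protein_pool = HierarchicalAttention(c.dt, rng, c.attention_levels,
                                                  c.attention_hidden)

        self.head = MLPHead(c.dc + c.dt, c.head_dims, rng, c.dropout)

    # -- branch computations -------------------------------------------------
    def drug_features(self, batch: ModelInputs) -> TokenFeatureMatrix:
        """Fused drug token features f_d."""
        mask = batch.drug_tokens.mask
        mcol = Tensor(mask[..., None])
        x = self.wd(batch.drug_tokens.tensor()) * mcol
        for layer in self.drug_encoder:
            x = layer(x, mask)
        fs = TokenFeatureMatrix(values=self.drug_norm(x) * mcol, mask=mask)
        return fuse_drug(fs, batch.morgan, batch.avalon,
                         self.fusion_morgan, self.fusion_avalon)

    def protein_features(self, batch: ModelInputs) -> TokenFeatureMatrix:
        """Fused protein residue features f_t."""
        mask = batch.protein_tokens.mask
        mcol = Tensor(mask[..., None])
        x = self.wp(batch.protein_tokens.tensor()) * mcol
        for layer in self.protein_encoder:
            x = layer(x, mask)
        fp = TokenFeatureMatrix(values=self.protein_norm(x) * mcol, mask=mask)
        fmer = self.kmer_norm(self.kmer_pooler(batch.kmer))
        wesm = esm_confidence(fp)
        return residual_fuse(fp, fmer, wesm, self.residual_fusion)

    def __call__(self, batch: ModelInputs) -> Tensor:
        """Predicted affinities, shape (batch,)."""
        fd = self.drug_features(batch)
        ft = self.protein_features(batch)
        pooled = concat([self.drug_pool(fd), self.protein_pool(ft)], axis=-1)
        return self.head(pooled).reshape(pooled.shape[0])
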