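"""Training, evaluation, cross-validation, checkpointing and attention export.

Featurization is computed once per unique drug/protein and cached; the
protein k-mer transforms (vocabulary, scaler, PCA) are fitted on training
proteins only and carried in the checkpoint alongside the network weights,
so a saved model reproduces its predictions exactly.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import no_grad
from .containers import TokenFeatureMatrix
from .data import AffinityDataset, make_repeats, split as split_dataset
from .embedders import get_embedder, pad_batch
from .errors import EmptyInputError, LeakageError
from .fingerprints import fingerprint
from .kmer import ProteinKmerFeaturizer
from .metrics import MetricsReport, evaluate_predictions
from .model import MGFDTAModel, ModelConfig, ModelInputs
from .nn import Adam, ReduceLROnPlateau

__all__ = ["FeatureCache", "TrainedModel", "train", "predict", "evaluate",
           "repeated_cv", "save_checkpoint", "load_checkpoint", "export_attention"]

logger = logging.getLogger(__name__)

_CHECKPOINT_VERSION = 1


class FeatureCache:
    """Per-entity frozen features: embeddings, fingerprints, k-mer vectors."""

    def __init__(self, config: ModelConfig, featurizer: ProteinKmerFeaturizer):
        if not featurizer.is_fitted:
            raise EmptyInputError("featurizer must be fitted before caching")
        if featurizer.provenance.get("fitted_on") != "train":
            raise LeakageError(
                "k-mer transforms must be fitted on the training split only "
                f"(got provenance {featurizer.provenance!r})")
        self.config = config
        self.featurizer = featurizer
        self.drug_embedder = get_embedder(config.drug_backend, "drug",
                                          config.drug_embed_dim, config.seed)
        self.protein_embedder = get_embedder(config.protein_backend, "protein",
                                             config.protein_embed_dim, config.seed)
        self._drug: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._protein: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _drug_entry(self, smiles: str):
        if smiles not in self._drug:
            emb = self.drug_embedder.embed(smiles)
            mor = fingerprint(smiles, "morgan", self.config.morgan_bits,
                              self.config.morgan_radius).bits
            ava = fingerprint(smiles, "avalon", self.config.avalon_bits).bits
            self._drug[smiles] = (emb, mor.astype(float), ava.astype(float))
        return self._drug[smiles]

    def _protein_entry(self, sequence: str):
        if sequence not in self._protein:
            emb = self.protein_embedder.embed(sequence)
            vec = self.featurizer.transform([sequence])[0]
            # rank-clamped PCA output is zero-padded up to the configured dim
            full = np.zeros(self.config.pca_dim)
            full[: vec.shape[0]] = vec[: self.config.pca_dim]
            self._protein[sequence] = (emb, full)
        return self._protein[sequence]

    def batch(self, rows: pd.DataFrame) -> ModelInputs:
        drug = [self._drug_entry(s) for s in rows["smiles"]]
        prot = [self._protein_entry(s) for s in rows["sequence"]]
        return ModelInputs(
            drug_tokens=pad_batch([d[0] for d in drug]),
            morgan=np.vstack([d[1] for d in drug]),
            avalon=np.vstack([d[2] for d in drug]),
            protein_tokens=pad_batch([p[0] for p in prot]),
            kmer=np.vstack([p[1] for p in prot]),
        )


@dataclass
class TrainedModel:
    model: MGFDTAModel
    config: ModelConfig
    featurizer: ProteinKmerFeaturizer
    log: list[dict] = field(default_factory=list)
    label_mean: float = 0.0   # train-split label statistics; the network
    label_sd: float = 1.0     # regresses standardized targets

    def cache(self) -> FeatureCache:
        return FeatureCache(self.config, self.featurizer)


def _check_split_disjoint(pairs: pd.DataFrame) -> None:
    names = pairs["split"].dropna().unique()
    seen: set[tuple] = set()
    for name in names:
        idx = {(r.drug_id, r.protein_id)
               for r in pairs[pairs["split"] == name].itertuples()}
        if seen & idx:
            raise LeakageError(f"split {name!r} overlaps a previous split")
        seen |= idx


def train(dataset: AffinityDataset, config: ModelConfig,
          cache: FeatureCache | None = None) -> TrainedModel:
    """Train the full network with Adam + plateau lr scheduling.

    The best-validation-MSE parameters are retained. All randomness
    (initialization, shuffling, dropout) derives from ``config.seed``.
    """
    if dataset.pairs["split"].isna().all():
        dataset = split_dataset(dataset, seed=config.seed)
    _check_split_disjoint(dataset.pairs)
    train_rows = dataset.subset("train")
    valid_rows = dataset.subset("valid")
    if len(train_rows) == 0 or len(valid_rows) == 0:
        raise EmptyInputError("train and valid splits must both be non-empty")

    if cache is None:
        featurizer = ProteinKmerFeaturizer(
            k=config.kmer_k, vocab_size=config.kmer_vocab_size,
            pca_dim=config.pca_dim)
        featurizer.fit(sorted(train_rows["sequence"].unique()), provenance="train")
        cache = FeatureCache(config, featurizer)

    model = MGFDTAModel(config)
    optimizer = Adam(model.parameters(), lr=config.lr)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.scheduler_factor,
                                  patience=config.scheduler_patience)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    y_train = train_rows["label"].to_numpy(float)
    y_valid = valid_rows["label"].to_numpy(float)
    if config.standardize_labels:
        y_mu = float(y_train.mean())
        y_sd = float(y_train.std()) or 1.0
    else:
        y_mu, y_sd = 0.0, 1.0
    y_train_s = (y_train - y_mu) / y_sd
    best = {"mse": np.inf, "state": model.state_dict()}
    log: list[dict] = []

    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        model.train()
        # shuffle, then bucket by protein length so batches carry little
        # padding; batch order is itself shuffled
        order = shuffle_rng.permutation(len(train_rows))
        lengths = train_rows["sequence"].str.len().to_numpy()
        order = order[np.argsort(lengths[order], kind="stable")]
        starts = np.arange(0, len(order), config.batch_size)
        losses = []
        for lo in shuffle_rng.permutation(starts):
            idx = order[lo: lo + config.batch_size]
            batch = cache.batch(train_rows.iloc[idx])
            target = y_train_s[idx]
            pred = model(batch)
            loss = ((pred - target) ** 2).mean()
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item() * y_sd ** 2)  # log in label units
        valid_pred = _predict_rows(model, cache, valid_rows,
                                   config.batch_size) * y_sd + y_mu
        valid_mse = float(np.mean((valid_pred - y_valid) ** 2))
        scheduler.step(valid_mse)
        if valid_mse < best["mse"]:
            best = {"mse": valid_mse, "state": model.state_dict()}
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "valid_mse": valid_mse, "lr": optimizer.lr,
                 "seconds": time.perf_counter() - t0}
        log.append(entry)
        logger.info("epoch %(epoch)d train %(train_loss).4f valid %(valid_mse).4f "
                    "lr %(lr).2e (%(seconds).1fs)", entry)

    model.load_state_dict(best["state"])
    model.eval()
    return TrainedModel(model=model, config=config, featurizer=cache.featurizer,
                        log=log, label_mean=y_mu, label_sd=y_sd)


def _predict_rows(model: MGFDTAModel, cache: FeatureCache, rows: pd.DataFrame,
                  batch_size: int) -> np.ndarray:
    model.eval()
    order = np.argsort(rows["sequence"].str.len().to_numpy(), kind="stable")
    out = np.empty(len(rows))
    with no_grad():
        for lo in range(0, len(rows), batch_size):
            idx = order[lo: lo + batch_size]
            out[idx] = model(cache.batch(rows.iloc[idx])).data
    model.train()
    return out


def predict(trained: TrainedModel, rows: pd.DataFrame,
            cache: FeatureCache | None = None) -> np.ndarray:
    """Deterministic eval-mode predictions for a pair table."""
    cache = cache or trained.cache()
    preds = _predict_rows(trained.model, cache, rows, trained.config.batch_size)
    trained.model.eval()
    return preds * trained.label_sd + trained.label_mean


def evaluate(trained: TrainedModel, rows: pd.DataFrame,
             cache: FeatureCache | None = None) -> MetricsReport:
    preds = predict(trained, rows, cache)
    return evaluate_predictions(rows["label"].to_numpy(float), preds)


def repeated_cv(dataset: AffinityDataset, config: ModelConfig, repeats: int = 5,
                folds: int = 5) -> list[MetricsReport]:
    """Repeated cross-validation: one report per (repeat, fold).

    Each repeat holds out a fresh seeded test fraction, runs ``folds``-fold
    CV on the rest, and every fold's model is scored on its held-out fold.
    The k-mer transforms are refitted inside every fold (training proteins
    only), so no fold ever sees statistics from its evaluation pairs.
    """
    schedule = make_repeats(dataset, repeats=repeats, folds=folds,
                            seed=config.seed)
    reports = []
    for entry in schedule:
        pairs = dataset.pairs.copy()
        pairs["split"] = pd.NA
        pairs.iloc[entry["train"], pairs.columns.get_loc("split")] = "train"
        pairs.iloc[entry["valid"], pairs.columns.get_loc("split")] = "valid"
        pairs.iloc[entry["test"], pairs.columns.get_loc("split")] = "test"
        fold_ds = AffinityDataset(pairs=pairs, provenance=dict(dataset.provenance))
        fold_cfg = ModelConfig.from_dict(
            dict(config.to_dict(), seed=config.seed + 1000 * entry["repeat"]))
        trained = train(fold_ds, fold_cfg)
        reports.append(evaluate(trained, fold_ds.subset("valid")))
    return reports


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(trained: TrainedModel, directory: str | Path) -> None:
    """Versioned archive: JSON manifest + parameter blobs + transforms."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": _CHECKPOINT_VERSION,
        "config": trained.config.to_dict(),
        "label_mean": trained.label_mean,
        "label_sd": trained.label_sd,
        "log": trained.log,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savez(directory / "params.npz", **trained.model.state_dict())
    trained.featurizer.save(directory / "kmer_transforms.npz")


def load_checkpoint(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["version"] != _CHECKPOINT_VERSION:
        raise EmptyInputError(
            f"unsupported checkpoint version {manifest['version']}")
    config = ModelConfig.from_dict(manifest["config"])
    model = MGFDTAModel(config)
    with np.load(directory / "params.npz") as arc:
        model.load_state_dict({k: arc[k] for k in arc.files})
    model.eval()
    featurizer = ProteinKmerFeaturizer.load(directory / "kmer_transforms.npz")
    return TrainedModel(model=model, config=config, featurizer=featurizer,
                        log=manifest["log"],
                        label_mean=manifest.get("label_mean", 0.0),
                        label_sd=manifest.get("label_sd", 1.0))


# -- interpretability --------------------------------------------------------

def export_attention(trained: TrainedModel, proteins: pd.DataFrame,
                     out_path: str | Path,
                     cache: FeatureCache | None = None) -> pd.DataFrame:
    """Per-residue protein attention weights (mean over levels + per level).

    ``proteins`` needs columns ``protein_id`` and ``sequence``; drugs do not
    enter the protein pooling weights. Writes a CSV with 1-based positions
    and returns the same table. High-weight residues are the model's
    candidate interaction sites.
    """
    cache = cache or trained.cache()
    model = trained.model
    model.eval()
    rows = []
    with no_grad():
        for rec in proteins.itertuples():
            emb = cache.protein_embedder.embed(rec.sequence)
            kvec = cache._protein_entry(rec.sequence)[1][None, :]
            batch_like = _protein_only_inputs(emb, kvec)
            ft = model.protein_features(batch_like)
            weights = model.protein_pool.export_weights(ft)
            n_valid = int(ft.mask[0].sum())
            for pos in range(n_valid):
                rows.append({
                    "protein_id": rec.protein_id,
                    "position": pos + 1,
                    "residue": rec.sequence[pos],
                    "mean_weight": weights["mean"][0, pos],
                    **{f"level_{i}": weights["per_level"][i, 0, pos]
                       for i in range(weights["per_level"].shape[0])},
                })
    df = pd.DataFrame(rows)
    with open(out_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(df.columns))
        writer.writeheader()
        writer.writerows(df.to_dict("records"))
    return df


def _protein_only_inputs(protein_emb: np.ndarray, kmer_vec: np.ndarray) -> ModelInputs:
    """Wrap a single protein into ModelInputs with a placeholder drug."""
    dummy = np.zeros((1, 1, 1))
    return ModelInputs(
        drug_tokens=TokenFeatureMatrix(values=dummy, mask=np.ones((1, 1))),
        morgan=np.zeros((1, 1)), avalon=np.zeros((1, 1)),
        protein_tokens=pad_batch([protein_emb]), kmer=kmer_vec)
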