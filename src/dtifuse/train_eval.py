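"""Splitting protocol, training loop, metrics and candidate ranking.

The evaluation protocol holds out a fixed 10% test set, then rotates the
remaining pool through 10 cross-validation folds (one tenth validation,
nine tenths training per fold).  Training runs minibatch Adam on the
mean binary cross-entropy; after each epoch the model is scored on the
validation set and the parameters of the best validation-AUC epoch are
retained.  Metrics: rank-based ROC AUC, area under the precision–recall
curve, and accuracy/precision/recall at a configurable threshold
(default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, average_precision_score,
                             precision_score, recall_score, roc_auc_score)

from .featurize import (FeaturizedPair, InvalidInputError, SmilesParseError,
                        encode_protein_sequence, make_kmer_tokens,
                        smiles_to_graph, tokenize_smiles, default_kmer_cap)
from .model import (DTIModel, InteractionRecord, ModelConfig, PredictionBatch)

N_FOLDS = 10
TEST_FRACTION = 0.10


@dataclass
class SplitPlan:
    """Fixed test indices plus 10 rotating train/validation folds."""

    test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]   # (train, validation)


@dataclass
class Metrics:
    auc: float
    aupr: float
    acc: float
    precision: float
    recall: float
    threshold: float
    ranking_defined: bool = True     # false when labels are single-class

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 50
    seed: int = 0
    lr: float = 1e-3
    d: int = 64
    T: int = 2
    k: int = 2
    fusion_mode: str = "hmsa"        # hmsa | concat | cross_attention
    message_fn: str = "mean"
    L_smiles: int = 150
    L_protein: int = 1000
    dropout: float = 0.1
    threshold: float = 0.5
    pos_weight: float = 1.0          # optional positive-class loss weight

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidInputError("epochs and batch_size must be >= 1")

    def model_config(self) -> ModelConfig:
        return ModelConfig(d=self.d, T=self.T, k=self.k,
                           L_smiles=self.L_smiles, L_protein=self.L_protein,
                           fusion_mode=self.fusion_mode,
                           message_fn=self.message_fn, dropout=self.dropout,
                           seed=self.seed)


def make_splits(n: int, seed: int) -> SplitPlan:
    """Deterministic split: 10% test, remaining pool in 10 rotating folds."""
    if n < 20:
        raise InvalidInputError(f"need at least 20 records, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = round(n * TEST_FRACTION)
    test = np.sort(perm[:n_test])
    pool = perm[n_test:]
    chunks = np.array_split(pool, N_FOLDS)
    folds = []
    for i in range(N_FOLDS):
        val = np.sort(chunks[i])
        train = np.sort(np.concatenate([chunks[j] for j in range(N_FOLDS)
                                        if j != i]))
        folds.append((train, val))
    return SplitPlan(test=test, folds=folds)


def evaluate(batch: PredictionBatch, threshold: float = 0.5) -> Metrics:
    """Compute AUC/AUPR plus thresholded accuracy, precision and recall.

    With single-class labels the ranking metrics are undefined and
    flagged as such (NaN); thresholded metrics are still returned.
    """
    if batch.labels is None:
        raise InvalidInputError("evaluation requires labels")
    keep = ~np.isnan(batch.probabilities)
    y = np.asarray(batch.labels, dtype=int)[keep]
    s = batch.probabilities[keep]
    pred = (s >= threshold).astype(int)
    acc = accuracy_score(y, pred)
    prec = precision_score(y, pred, zero_division=0)
    rec = recall_score(y, pred, zero_division=0)
    if len(np.unique(y)) < 2:
        return Metrics(math.nan, math.nan, acc, prec, rec, threshold,
                       ranking_defined=False)
    return Metrics(float(roc_auc_score(y, s)),
                   float(average_precision_score(y, s)),
                   float(acc), float(prec), float(rec), threshold)


class FeatureCache:
    """Per-entity featurization cache shared across epochs and folds."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self._drugs: dict[str, tuple] = {}
        self._prots: dict[str, tuple] = {}

    def get(self, rec: InteractionRecord) -> FeaturizedPair:
        c = self.config
        if rec.smiles not in self._drugs:
            self._drugs[rec.smiles] = (tokenize_smiles(rec.smiles, c.L_smiles),
                                       smiles_to_graph(rec.smiles))
        if rec.sequence not in self._prots:
            self._prots[rec.sequence] = (
                encode_protein_sequence(rec.sequence, c.L_protein),
                make_kmer_tokens(rec.sequence, c.k,
                                 default_kmer_cap(c.k, c.L_protein)))
        st, g = self._drugs[rec.smiles]
        qt, mt = self._prots[rec.sequence]
        return FeaturizedPair(st, g, qt, mt)


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_auc: float


@dataclass
class TrainResult:
    model: DTIModel
    history: list[EpochLog]
    best_epoch: int                  # 1-based; 0 when no validation was used


class NaNLossError(RuntimeError):
    def __init__(self, epoch: int, batch_ids: list[int]):
        super().__init__(f"NaN loss in epoch {epoch}, batch indices {batch_ids}")
        self.batch_ids = batch_ids


def train_on_records(config: TrainConfig,
                     train_records: list[InteractionRecord],
                     val_records: list[InteractionRecord] | None = None,
                     cache: FeatureCache | None = None) -> TrainResult:
    """Minibatch training with best-on-validation checkpointing.

    Without a validation set the final-epoch parameters are kept.
    Deterministic for a fixed config (all randomness flows from
    ``config.seed``).
    """
    mc = config.model_config()
    model = DTIModel(mc)
    cache = cache or FeatureCache(mc)
    feats = [cache.get(r) for r in train_records]
    labels = np.array([r.label for r in train_records], dtype=float)
    val_feats = ([cache.get(r) for r in val_records] if val_records else None)
    val_labels = (np.array([r.label for r in val_records], dtype=float)
                  if val_records else None)
    opt = model.make_optimizer(lr=config.lr)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history: list[EpochLog] = []
    best_auc, best_epoch, best_state = -np.inf, 0, None
    n = len(feats)
    for epoch in range(1, config.epochs + 1):
        model.training = True
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = [feats[i] for i in idx]
            loss = model.loss(batch, labels[idx], reduction="mean",
                              pos_weight=config.pos_weight)
            if not np.isfinite(loss.data):
                raise NaNLossError(epoch, idx.tolist())
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.training = False
        val_auc = math.nan
        if val_feats:
            scores = _score_feats(model, val_feats)
            if len(np.unique(val_labels)) > 1:
                val_auc = float(roc_auc_score(val_labels, scores))
            if val_auc > best_auc or best_state is None:
                best_auc, best_epoch = val_auc, epoch
                best_state = model.store.state_dict()
        history.append(EpochLog(epoch, float(np.mean(losses)), val_auc))
    if best_state is not None:
        model.store.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def _score_feats(model: DTIModel, feats: list[FeaturizedPair],
                 batch_size: int = 64) -> np.ndarray:
    out = []
    for lo in range(0, len(feats), batch_size):
        out.append(model.forward(feats[lo:lo + batch_size]).data)
    return np.concatenate(out)


def score_records(model: DTIModel, records: list[InteractionRecord],
                  cache: FeatureCache | None = None) -> np.ndarray:
    """Evaluation-mode probabilities for records (all must featurize)."""
    model.training = False
    cache = cache or FeatureCache(model.config)
    return _score_feats(model, [cache.get(r) for r in records])


def train(config: TrainConfig, records: list[InteractionRecord],
          fold: tuple[np.ndarray, np.ndarray],
          cache: FeatureCache | None = None) -> TrainResult:
    """Train one cross-validation fold given (train, validation) indices."""
    tr, va = fold
    return train_on_records(config,
                            [records[i] for i in tr],
                            [records[i] for i in va], cache=cache)


def rank_candidates(model: DTIModel, anchor: InteractionRecord,
                    candidates: list[InteractionRecord],
                    top_n: int = 20) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Score (anchor, candidate) pairs and return the top-n ranking.

    ``anchor`` supplies the fixed entity: candidates each override the
    other side.  Ties are broken by input order (stable sort).  Invalid
    candidates land in the rejects report.
    """
    if not candidates:
        raise InvalidInputError("no candidates supplied")
    pairs = []
    for c in candidates:
        pairs.append(InteractionRecord(
            smiles=c.smiles or anchor.smiles,
            sequence=c.sequence or anchor.sequence,
            drug_id=c.drug_id or anchor.drug_id,
            protein_id=c.protein_id or anchor.protein_id))
    batch = model.predict_pairs(pairs)
    scored = [(i, p) for i, p in enumerate(batch.probabilities)
              if not np.isnan(p)]
    order = sorted(scored, key=lambda t: (-t[1], t[0]))[:top_n]
    table = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "candidate_index": [i for i, _ in order],
        "drug_id": [pairs[i].drug_id for i, _ in order],
        "protein_id": [pairs[i].protein_id for i, _ in order],
        "smiles": [pairs[i].smiles for i, _ in order],
        "sequence": [pairs[i].sequence for i, _ in order],
        "score": [s for _, s in order],
    })
    return table, batch.rejects
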