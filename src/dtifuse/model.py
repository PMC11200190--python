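"""End-to-end drug–target interaction predictor.

Wiring: four featurized modality streams -> embeddings -> CNN blocks
(token streams) / D-MPNN (molecular graph) -> hierarchical multimodal
self-attention fusion -> four pooled Z vectors -> a four-layer fully
connected classifier (dropout + LeakyReLU after the first three layers,
sigmoid on the final logit) -> interaction probability, trained with
binary cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import ParamStore, Adam
from .featurize import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM, FeaturizedPair,
                        InvalidInputError, SmilesParseError, featurize_pair,
                        kmer_vocab_size, DEFAULT_L_SMILES, DEFAULT_L_PROTEIN)
from .encoders import cnn_core, dmpnn_core
from .fusion import AttentionWeights, fuse_streams_tensor

EPS = 1e-7


@dataclass
class InteractionRecord:
    """One (drug, protein) pair with an optional binary label."""

    smiles: str
    sequence: str
    label: int | None = None
    drug_id: str = ""
    protein_id: str = ""


@dataclass
class ClassifierParams:
    """Four-layer funnel classifier; final layer emits a single logit."""

    weights: list[np.ndarray]       # 4 matrices: 4d->h1->h2->h3->1
    biases: list[np.ndarray]
    dropout: float = 0.1
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if len(self.weights) != 4 or len(self.biases) != 4:
            raise ValueError("classifier must have exactly four layers")


@dataclass
class PredictionBatch:
    """Ordered probabilities for scored records plus a rejects report."""

    probabilities: np.ndarray
    labels: np.ndarray | None = None
    pair_ids: list[tuple[str, str]] = field(default_factory=list)
    rejects: list[tuple[int, str]] = field(default_factory=list)


def classifier_hidden_sizes(d: int) -> tuple[int, int, int]:
    """Funnel widths; scaled down for small desk-run model dims (d <= 32)."""
    if d <= 32:
        return (8 * d, 4 * d, 2 * d)
    return (1024, 512, 256)


def classifier_forward(z_concat: np.ndarray, p: ClassifierParams,
                       training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Probability for concatenated pooled features (..., 4d).

    Dropout and LeakyReLU follow layers 1–3 only; the final linear layer
    feeds a sigmoid directly so the output is a proper probability.
    Dropout is inactive when ``training`` is false.
    """
    h = np.asarray(z_concat, dtype=np.float64)
    if h.shape[-1] != p.weights[0].shape[0]:
        raise ValueError("classifier input width mismatch")
    for i in range(3):
        h = h @ p.weights[i] + p.biases[i]
        if training and p.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            keep = rng.random(h.shape) >= p.dropout
            h = h * keep / (1.0 - p.dropout)
        h = np.where(h > 0, h, p.negative_slope * h)
    logit = h @ p.weights[3] + p.biases[3]
    return 1.0 / (1.0 + np.exp(-logit))


def bce_loss(t, p, reduction: str = "sum") -> float:
    """Binary cross-entropy over a prediction batch.

    ``reduction="sum"`` is the literal summed form; ``"mean"`` divides by
    n (the training default for step-size stability).  Probabilities are
    clipped to [eps, 1-eps] with eps = 1e-7.
    """
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if not np.isin(t, (0.0, 1.0)).all():
        raise InvalidInputError("labels must be 0 or 1")
    if reduction not in ("sum", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    pc = np.clip(p, EPS, 1.0 - EPS)
    loss = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).sum()
    return float(loss / len(t)) if reduction == "mean" else float(loss)


@dataclass
class ModelConfig:
    d: int = 64
    T: int = 2
    k: int = 2
    L_smiles: int = DEFAULT_L_SMILES
    L_protein: int = DEFAULT_L_PROTEIN
    cnn_kernels: tuple[int, ...] = (3, 5, 7)
    message_fn: str = "mean"
    fusion_mode: str = "hmsa"       # hmsa | concat | cross_attention
    n_heads: int = 1
    dropout: float = 0.1
    negative_slope: float = 0.01
    seed: int = 0

    def to_json(self) -> str:
        cfg = asdict(self)
        cfg["cnn_kernels"] = list(self.cnn_kernels)
        return json.dumps(cfg, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        cfg = json.loads(text)
        cfg["cnn_kernels"] = tuple(cfg["cnn_kernels"])
        return cls(**cfg)


class DTIModel:
    """Trainable four-modality interaction predictor."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        d = config.d
        store = ParamStore(self.rng, dtype=np.float32)
        self.store = store
        # embeddings (row 0 = padding, pinned to zero)
        store.embedding("emb_smiles", 65, d)
        store.embedding("emb_seq", 23, d)
        store.embedding("emb_mer", kmer_vocab_size(config.k) + 1, d)
        # CNN stacks per token stream
        for stream in ("smiles", "seq", "mer"):
            for i, ksz in enumerate(config.cnn_kernels):
                store.conv_kernel(f"cnn_{stream}_w{i}", ksz, d, d)
                store.bias(f"cnn_{stream}_b{i}", d)
        # D-MPNN
        store.dense("mpnn_W_b", ATOM_FEATURE_DIM + BOND_FEATURE_DIM, d)
        store.dense("mpnn_W_x", ATOM_FEATURE_DIM, d)
        store.dense("mpnn_W_f", 2 * d, d)
        store.bias("mpnn_b_f", d)
        store.dense("mpnn_W_alpha", ATOM_FEATURE_DIM + d, d)
        store.bias("mpnn_b_alpha", d)
        # attention parameter sets: level-1 drug, level-1 protein, level-2
        for name in ("att1d", "att1p", "att2"):
            for proj in ("Q", "K", "V"):
                store.dense(f"{name}_W_{proj}", d, d)
                store.bias(f"{name}_b_{proj}", d)
        # classifier funnel
        h1, h2, h3 = classifier_hidden_sizes(d)
        dims = [4 * d, h1, h2, h3, 1]
        for i in range(4):
            store.dense(f"clf_W{i}", dims[i], dims[i + 1])
            store.bias(f"clf_b{i}", dims[i + 1])
        self._frozen_rows = {"emb_smiles": 0, "emb_seq": 0, "emb_mer": 0}
        self.training = False

    # -- plumbing ---------------------------------------------------------
    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.store, lr=lr, frozen_rows=self._frozen_rows)

    def _attention_weights(self, name: str) -> AttentionWeights:
        s = self.store
        return AttentionWeights(s[f"{name}_W_Q"], s[f"{name}_W_K"],
                                s[f"{name}_W_V"], s[f"{name}_b_Q"],
                                s[f"{name}_b_K"], s[f"{name}_b_V"],
                                self.config.n_heads)

    def featurize(self, rec: InteractionRecord) -> FeaturizedPair:
        return featurize_pair(rec.smiles, rec.sequence, k=self.config.k,
                              L_smiles=self.config.L_smiles,
                              L_protein=self.config.L_protein)

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _batch_tokens(tokvecs, pad_to: int | None = None):
        """Stack token vectors trimmed to the batch-max true length."""
        L = max(tv.true_length for tv in tokvecs)
        L = max(L, 1) if pad_to is None else max(L, pad_to)
        ids = np.zeros((len(tokvecs), L), dtype=np.int64)
        for i, tv in enumerate(tokvecs):
            n = min(tv.true_length, L)
            ids[i, :n] = tv.ids[:n]
        return ids, ids != 0

    def _encode_tokens(self, ids: np.ndarray, mask: np.ndarray,
                       emb_name: str, cnn_name: str) -> Tensor:
        x = ad.gather(self.store[emb_name], ids)
        x = ad.where_mask(mask, x)
        kernels = [self.store[f"cnn_{cnn_name}_w{i}"]
                   for i in range(len(self.config.cnn_kernels))]
        biases = [self.store[f"cnn_{cnn_name}_b{i}"]
                  for i in range(len(self.config.cnn_kernels))]
        return cnn_core(x, kernels, biases, mask)

    def _encode_graphs(self, graphs) -> tuple[Tensor, np.ndarray]:
        """Disjoint-union D-MPNN over a batch, scattered to (B, Lg, d)."""
        counts = [g.n_atoms for g in graphs]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        n_total = int(offsets[-1])
        atom = np.concatenate([g.atom_features for g in graphs],
                              axis=0).astype(np.float32)
        bond = np.concatenate([g.bond_features for g in graphs],
                              axis=0).astype(np.float32)
        src = np.concatenate([g.edge_src + offsets[i]
                              for i, g in enumerate(graphs)])
        dst = np.concatenate([g.edge_dst + offsets[i]
                              for i, g in enumerate(graphs)])
        rev = np.concatenate([g.rev_edge + off for g, off in
                              zip(graphs, np.concatenate(
                                  [[0], np.cumsum([g.n_edges for g in graphs])]
                              )[:-1])]).astype(np.int64)
        s = self.store
        nodes = dmpnn_core(Tensor(atom), Tensor(bond), src.astype(np.int64),
                           dst.astype(np.int64), rev,
                           s["mpnn_W_b"], s["mpnn_W_x"], s["mpnn_W_f"],
                           s["mpnn_b_f"], s["mpnn_W_alpha"], s["mpnn_b_alpha"],
                           self.config.T, self.config.message_fn)
        # pad with one zero row, then gather into the (B, Lg_max) layout
        Lg = max(counts)
        zero_row = Tensor(np.zeros((1, self.config.d), dtype=np.float32))
        padded = ad.concat([nodes, zero_row], axis=0)
        idx = np.full((len(graphs), Lg), n_total, dtype=np.int64)
        mask = np.zeros((len(graphs), Lg), dtype=bool)
        for i, c in enumerate(counts):
            idx[i, :c] = np.arange(offsets[i], offsets[i] + c)
            mask[i, :c] = True
        return ad.gather(padded, idx), mask

    def forward(self, pairs: Sequence[FeaturizedPair]) -> Tensor:
        """Probabilities (B,) for a batch of featurized records."""
        ids_s, m_s = self._batch_tokens([p.smiles_tokens for p in pairs])
        ids_q, m_q = self._batch_tokens([p.seq_tokens for p in pairs])
        ids_m, m_m = self._batch_tokens([p.mer_tokens for p in pairs])
        Xs = self._encode_tokens(ids_s, m_s, "emb_smiles", "smiles")
        Xq = self._encode_tokens(ids_q, m_q, "emb_seq", "seq")
        Xm = self._encode_tokens(ids_m, m_m, "emb_mer", "mer")
        Xg, m_g = self._encode_graphs([p.graph for p in pairs])
        Zs, Zg, Zq, Zm = fuse_streams_tensor(
            Xs, Xg, Xq, Xm, (m_s, m_g, m_q, m_m),
            self._attention_weights("att1d"),
            self._attention_weights("att1p"),
            self._attention_weights("att2"),
            mode=self.config.fusion_mode)
        h = ad.concat([Zs, Zg, Zq, Zm], axis=-1)
        for i in range(3):
            h = h.__matmul__(self.store[f"clf_W{i}"]) + self.store[f"clf_b{i}"]
            if self.training and self.config.dropout > 0:
                keep = (self.rng.random(h.shape) >= self.config.dropout)
                h = h * (keep / (1.0 - self.config.dropout)).astype(h.data.dtype)
            h = h.leaky_relu(self.config.negative_slope)
        logit = h.__matmul__(self.store["clf_W3"]) + self.store["clf_b3"]
        return logit.reshape(len(pairs)).sigmoid()

    def loss(self, pairs: Sequence[FeaturizedPair], labels: np.ndarray,
             reduction: str = "mean", pos_weight: float = 1.0) -> Tensor:
        """Differentiable BCE loss for a featurized batch.

        ``pos_weight`` scales the positive-class term (an optional knob
        for 1:10-style unbalanced label designs; default 1 = unweighted).
        """
        p = self.forward(pairs).clip(EPS, 1.0 - EPS)
        labels = np.asarray(labels, dtype=p.data.dtype)
        one_minus = (p * -1.0) + 1.0
        terms = p.log() * (labels * pos_weight) + one_minus.log() * (1.0 - labels)
        total = terms.sum() * -1.0
        return total / len(pairs) if reduction == "mean" else total

    # -- inference --------------------------------------------------------
    def predict_pairs(self, records: Sequence[InteractionRecord],
                      batch_size: int = 64) -> PredictionBatch:
        """Score records in evaluation mode, preserving input order.

        Records whose SMILES fails to parse or whose sequence is invalid
        are collected into the rejects report; the rest are scored.
        """
        self.training = False
        feats, keep_idx, rejects = [], [], []
        for i, rec in enumerate(records):
            try:
                feats.append(self.featurize(rec))
                keep_idx.append(i)
            except (SmilesParseError, InvalidInputError, KeyError) as e:
                rejects.append((i, str(e)))
        probs = np.full(len(records), np.nan)
        for lo in range(0, len(feats), batch_size):
            chunk = feats[lo:lo + batch_size]
            out = self.forward(chunk).data
            for j, v in zip(keep_idx[lo:lo + batch_size], out):
                probs[j] = v
        labels = (np.array([r.label for r in records], dtype=float)
                  if all(r.label is not None for r in records) else None)
        return PredictionBatch(
            probabilities=probs, labels=labels,
            pair_ids=[(r.drug_id, r.protein_id) for r in records],
            rejects=rejects)

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **self.store.state_dict())
        side = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            fh.write(self.config.to_json())

    @classmethod
    def load(cls, path: str) -> "DTIModel":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            config = ModelConfig.from_json(fh.read())
        model = cls(config)
        with np.load(base + ".npz") as data:
            model.store.load_state_dict({k: data[k] for k in data.files})
        return model

    def classifier_params(self) -> ClassifierParams:
        return ClassifierParams(
            weights=[self.store[f"clf_W{i}"].data.copy() for i in range(4)],
            biases=[self.store[f"clf_b{i}"].data.copy() for i in range(4)],
            dropout=self.config.dropout,
            negative_slope=self.config.negative_slope)
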