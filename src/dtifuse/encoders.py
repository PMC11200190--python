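"""Modality encoders: token-CNN blocks and a readout-free D-MPNN.

Token streams (protein sequence, protein k-mer, SMILES) are embedded and
passed through a stack of same-padding 1-D convolutions with rectifier
activations, preserving the spatial length so every token keeps a feature
row.  Molecular graphs are encoded with a directed message-passing
network whose hidden states live on directed bonds; messages to edge
v->w aggregate over incoming neighbours of v *excluding* w, preventing
immediate back-flow.  The readout (graph pooling) stage is deliberately
absent: per-atom node features are returned so that atoms participate as
tokens in the downstream multimodal fusion.

Two faces are exposed: a functional NumPy API mirroring the individual
operations (used directly in analyses and tests), and Tensor-level cores
shared with the trainable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import MolecularGraph, TokenVector


@dataclass
class ModalFeatureMatrix:
    """L x d feature matrix with validity mask for one modality."""

    values: np.ndarray            # (L, d)
    mask: np.ndarray              # (L,) bool
    modality: str = "seq"         # smiles | graph | seq | mer

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[0] != self.mask.shape[0]:
            raise ValueError("values and mask length mismatch")


@dataclass
class EmbeddingTable:
    """vocab_size x d lookup table; row 0 (padding) is all zeros."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.allclose(self.weights[0], 0.0):
            raise ValueError("embedding row 0 (padding) must be zero")

    @property
    def vocab_size(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


@dataclass
class CnnBlockParams:
    """Same-padding convolution stack; final channel count is the model dim."""

    kernels: list[np.ndarray]     # each (K, C_in, C_out), K odd
    biases: list[np.ndarray]      # each (C_out,)

    @property
    def n_layers(self) -> int:
        return len(self.kernels)


@dataclass
class DmpnnParams:
    """Weights of the directed message-passing network.

    ``message_fn``: ``"mean"`` averages the projected endpoint atom
    features with the incoming edge hidden state; ``"edge_hidden_sum"``
    is the classical convention where the message is the plain sum of
    incoming edge hidden states.
    """

    W_b: np.ndarray               # (f_atom + f_bond, d) edge init
    W_x: np.ndarray               # (f_atom, d) atom projection inside M
    W_f: np.ndarray               # (2d, d) edge update
    b_f: np.ndarray               # (d,)
    W_alpha: np.ndarray           # (f_atom + d, d) node readout
    b_alpha: np.ndarray           # (d,)
    T: int = 2
    message_fn: str = "mean"

    def __post_init__(self) -> None:
        if self.message_fn not in ("mean", "edge_hidden_sum"):
            raise ValueError(f"unknown message_fn {self.message_fn!r}")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------- cores


def cnn_core(x: Tensor, kernels: list[Tensor], biases: list[Tensor],
             mask: np.ndarray) -> Tensor:
    """Convolution stack with ReLU; masked positions re-zeroed per layer."""
    h = x
    for w, b in zip(kernels, biases):
        h = ad.conv1d_same(h, w, b).relu()
        h = ad.where_mask(mask, h)
    return h


def _in_degree(edge_dst: np.ndarray, n_atoms: int) -> np.ndarray:
    return np.bincount(edge_dst, minlength=n_atoms).astype(np.float64)


def dmpnn_edge_init_core(atom: Tensor, bond: Tensor, edge_src: np.ndarray,
                         W_b: Tensor) -> Tensor:
    """h0 for every directed edge: ReLU(W_b [x_src ; e])."""
    if len(edge_src) == 0:
        return Tensor(np.zeros((0, W_b.shape[1])))
    x_src = ad.gather(atom, edge_src)
    return ad.concat([x_src, bond], axis=1).__matmul__(W_b).relu()


def dmpnn_message_core(h: Tensor, atom_proj: Tensor, edge_src: np.ndarray,
                       edge_dst: np.ndarray, rev_edge: np.ndarray,
                       n_atoms: int, message_fn: str) -> Tensor:
    """Per-edge message for edge v->w, aggregating N(v) \\ {w}.

    Vectorised as a scatter-sum over incoming edges minus the excluded
    reverse-edge term; an empty neighbour set yields a zero message.
    """
    h_rev = ad.gather(h, rev_edge)
    if message_fn == "edge_hidden_sum":
        S = ad.segment_sum(h, edge_dst, n_atoms)         # (N, d): sum of h_kv
        return ad.gather(S, edge_src) - h_rev
    # mean of (P_v, P_k, h_kv) over k in N(v)\{w}
    P_src = ad.gather(atom_proj, edge_src)               # P_k per edge (k->v)
    C = ad.segment_sum(P_src + h, edge_dst, n_atoms)     # (N, d)
    deg = _in_degree(edge_dst, n_atoms)
    P_v = ad.gather(atom_proj, edge_src)                 # P_v for edge (v->w)
    P_w = ad.gather(atom_proj, edge_dst)
    excess = (deg - 1.0)[edge_src][:, None].astype(h.data.dtype)
    return (P_v * excess + ad.gather(C, edge_src) - P_w - h_rev) / 3.0


def dmpnn_core(atom: Tensor, bond: Tensor, edge_src: np.ndarray,
               edge_dst: np.ndarray, rev_edge: np.ndarray,
               W_b: Tensor, W_x: Tensor, W_f: Tensor, b_f: Tensor,
               W_alpha: Tensor, b_alpha: Tensor, T: int,
               message_fn: str = "mean") -> Tensor:
    """Full D-MPNN pass returning per-atom node features (N, d)."""
    if T < 1:
        raise ConfigError("D-MPNN iteration count T must be >= 1")
    n_atoms = atom.shape[0]
    d = W_b.shape[1]
    if len(edge_src) == 0:
        m_v = Tensor(np.zeros((n_atoms, d), dtype=atom.data.dtype))
    else:
        h = dmpnn_edge_init_core(atom, bond, edge_src, W_b)
        atom_proj = atom.__matmul__(W_x)
        for _ in range(T):
            m = dmpnn_message_core(h, atom_proj, edge_src, edge_dst,
                                   rev_edge, n_atoms, message_fn)
            h = (ad.concat([h, m], axis=1).__matmul__(W_f) + b_f).relu()
        m_v = ad.segment_sum(h, edge_dst, n_atoms)
    return (ad.concat([atom, m_v], axis=1).__matmul__(W_alpha) + b_alpha).relu()


# ----------------------------------------------------- functional API


def embed_tokens(tokens: TokenVector, table: EmbeddingTable) -> ModalFeatureMatrix:
    """Look up embedding rows for a token vector; padded rows stay zero."""
    if tokens.ids.max(initial=0) >= table.vocab_size:
        raise IndexError("token id exceeds embedding vocabulary")
    values = table.weights[tokens.ids]
    values = np.where(tokens.mask[:, None], values, 0.0)
    return ModalFeatureMatrix(values, tokens.mask.copy())


def cnn_block(X: ModalFeatureMatrix, params: CnnBlockParams) -> ModalFeatureMatrix:
    """Apply the convolution stack; spatial length is preserved."""
    if X.values.shape[1] != params.kernels[0].shape[1]:
        raise ValueError(
            f"channel mismatch: input {X.values.shape[1]}, "
            f"kernel expects {params.kernels[0].shape[1]}")
    out = cnn_core(Tensor(X.values),
                   [Tensor(k) for k in params.kernels],
                   [Tensor(b) for b in params.biases], X.mask)
    return ModalFeatureMatrix(out.data, X.mask.copy(), X.modality)


def dmpnn_init_edges(g: MolecularGraph, p: DmpnnParams) -> np.ndarray:
    """Initial hidden state per directed edge (Eq-level entry point)."""
    if g.atom_features.shape[1] + g.bond_features.shape[1] != p.W_b.shape[0]:
        raise ValueError("atom+bond feature width does not match W_b")
    return dmpnn_edge_init_core(Tensor(g.atom_features), Tensor(g.bond_features),
                                g.edge_src, Tensor(p.W_b)).data


def dmpnn_iterate(g: MolecularGraph, h0: np.ndarray, p: DmpnnParams) -> np.ndarray:
    """Run T rounds of directed message passing from h0; returns h^T."""
    if p.T < 1:
        raise ConfigError("T must be >= 1")
    if g.n_edges == 0:
        return h0.copy()
    h = Tensor(h0)
    atom_proj = Tensor(g.atom_features).__matmul__(Tensor(p.W_x))
    W_f, b_f = Tensor(p.W_f), Tensor(p.b_f)
    for _ in range(p.T):
        m = dmpnn_message_core(h, atom_proj, g.edge_src, g.edge_dst,
                               g.rev_edge, g.n_atoms, p.message_fn)
        h = (ad.concat([h, m], axis=1).__matmul__(W_f) + b_f).relu()
    return h.data


def dmpnn_node_features(g: MolecularGraph, hT: np.ndarray,
                        p: DmpnnParams) -> ModalFeatureMatrix:
    """Aggregate final edge states into per-atom features; no pooling."""
    if g.n_edges:
        m_v = np.zeros((g.n_atoms, hT.shape[1]))
        np.add.at(m_v, g.edge_dst, hT)
    else:
        m_v = np.zeros((g.n_atoms, p.W_alpha.shape[1]))
    z = np.concatenate([g.atom_features, m_v], axis=1) @ p.W_alpha + p.b_alpha
    values = np.maximum(z, 0.0)
    return ModalFeatureMatrix(values, np.ones(g.n_atoms, dtype=bool), "graph")


def dmpnn_encode(g: MolecularGraph, p: DmpnnParams) -> ModalFeatureMatrix:
    """Convenience: init -> iterate -> node features."""
    out = dmpnn_core(Tensor(g.atom_features), Tensor(g.bond_features),
                     g.edge_src, g.edge_dst, g.rev_edge,
                     Tensor(p.W_b), Tensor(p.W_x), Tensor(p.W_f), Tensor(p.b_f),
                     Tensor(p.W_alpha), Tensor(p.b_alpha), p.T, p.message_fn)
    return ModalFeatureMatrix(out.data, np.ones(g.n_atoms, dtype=bool), "graph")
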