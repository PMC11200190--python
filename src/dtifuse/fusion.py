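"""Multimodal fusion: cross-attention and hierarchical self-attention.

Cross-attention (the ablation baseline) draws queries from one modality
and keys/values from another; its output rows are, by construction,
weighted combinations of the value rows — a linear transform of the
key/value modality only.  Hierarchical multimodal self-attention (HMSA)
instead stacks two modality token streams into one sequence and applies
scaled dot-product self-attention over the joint stream, so the
attention matrix decomposes into intra- and inter-modal blocks and the
output mixes both modalities.  Two levels are applied: drug-internal
(SMILES tokens + graph atoms) and protein-internal (sequence + 2-mer)
first, then the drug and protein streams jointly.  Outputs are split
back at the original segment boundaries, added to their residual inputs
and max-pooled over valid positions into the four Z vectors fed to the
classifier.

Padding handling: masked key columns receive -inf logits before softmax
(exactly zero attention mass), and masked query rows yield zero output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import ModalFeatureMatrix


class FusionInputError(ValueError):
    pass


@dataclass
class AttentionParams:
    """Single projection set for scaled dot-product attention."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    b_Q: np.ndarray
    b_K: np.ndarray
    b_V: np.ndarray
    n_heads: int = 1

    @property
    def d_att(self) -> int:
        return self.W_Q.shape[1]

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.d_att % self.n_heads:
            raise ValueError("head count must divide d_att")


@dataclass
class AttentionOutput:
    """Fused feature matrix H plus the attention weight matrix A.

    With multiple heads, ``A`` is stacked head-first: (n_heads, L_q, L_k).
    """

    H: np.ndarray
    A: np.ndarray


@dataclass
class FusionBundle:
    """Post-fusion matrices aligned with their input masks."""

    D_smiles: np.ndarray
    D_graph: np.ndarray
    D_seq: np.ndarray
    D_mer: np.ndarray


@dataclass
class PooledFeatures:
    """The four pooled modality vectors entering the classifier."""

    Z_smiles: np.ndarray
    Z_graph: np.ndarray
    Z_seq: np.ndarray
    Z_mer: np.ndarray


@dataclass
class AttentionWeights:
    """Tensor-valued attention projections (shared by model and wrappers)."""

    W_Q: Tensor
    W_K: Tensor
    W_V: Tensor
    b_Q: Tensor
    b_K: Tensor
    b_V: Tensor
    n_heads: int = 1

    @classmethod
    def from_params(cls, p: AttentionParams) -> "AttentionWeights":
        return cls(Tensor(p.W_Q), Tensor(p.W_K), Tensor(p.W_V),
                   Tensor(p.b_Q), Tensor(p.b_K), Tensor(p.b_V), p.n_heads)


def _swap_last(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(*axes)


def attention_core(Xq: Tensor, Xkv: Tensor, w: AttentionWeights,
                   q_mask: np.ndarray, k_mask: np.ndarray
                   ) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention with padding masks.

    Shapes: Xq (..., L_q, d), Xkv (..., L_k, d); masks (..., L_q) and
    (..., L_k).  Returns H (..., L_q, d_att) and the attention matrix A
    ((..., L_q, L_k) single-head; heads stacked on a new leading axis of
    the last two dims otherwise).
    """
    Q = Xq.__matmul__(w.W_Q) + w.b_Q
    K = Xkv.__matmul__(w.W_K) + w.b_K
    V = Xkv.__matmul__(w.W_V) + w.b_V
    d_att = w.W_Q.shape[1]
    h = w.n_heads
    key_mask = np.expand_dims(k_mask, -2)       # (..., 1, L_k)
    if h == 1:
        logits = Q.__matmul__(_swap_last(K)) / float(np.sqrt(d_att))
        A = ad.masked_softmax(logits, key_mask, axis=-1)
        A = ad.where_mask(q_mask, A)
        H = A.__matmul__(V)
    else:
        dh = d_att // h
        heads, As = [], []
        for i in range(h):
            sl = slice(i * dh, (i + 1) * dh)
            Qi, Ki, Vi = Q[..., sl], K[..., sl], V[..., sl]
            logits = Qi.__matmul__(_swap_last(Ki)) / float(np.sqrt(dh))
            Ai = ad.masked_softmax(logits, key_mask, axis=-1)
            Ai = ad.where_mask(q_mask, Ai)
            heads.append(Ai.__matmul__(Vi))
            As.append(Ai.reshape(*((1,) + Ai.shape)))
        H = ad.concat(heads, axis=-1)
        A = ad.concat(As, axis=0)
    H = ad.where_mask(q_mask, H)
    return H, A


# ----------------------------------------------------- functional API


def masked_self_attention(X: ModalFeatureMatrix,
                          p: AttentionParams) -> AttentionOutput:
    """Self-attention over one stream; masked keys get zero weight."""
    if X.values.shape[0] == 0 or not X.mask.any():
        raise FusionInputError("attention input has no unmasked positions")
    w = AttentionWeights.from_params(p)
    X_t = Tensor(X.values)
    H, A = attention_core(X_t, X_t, w, X.mask, X.mask)
    return AttentionOutput(H.data, A.data)


def cross_attention(Xq: ModalFeatureMatrix, Xkv: ModalFeatureMatrix,
                    p: AttentionParams) -> AttentionOutput:
    """Queries from one modality, keys/values from the other."""
    if Xkv.values.shape[0] == 0 or not Xkv.mask.any():
        raise FusionInputError("empty key/value stream")
    if Xq.values.shape[1] != Xkv.values.shape[1]:
        raise ValueError("query and key/value streams must share width d")
    w = AttentionWeights.from_params(p)
    H, A = attention_core(Tensor(Xq.values), Tensor(Xkv.values), w,
                          Xq.mask, Xkv.mask)
    return AttentionOutput(H.data, A.data)


def hmsa_level(Xa: ModalFeatureMatrix, Xb: ModalFeatureMatrix,
               p: AttentionParams, return_attention: bool = False):
    """One fusion level: self-attention over the stacked stream [Xa; Xb].

    The joint attention matrix realises all four intra/inter blocks;
    the output splits back at the boundary into (Ha, Hb).
    """
    if Xa.values.shape[1] != Xb.values.shape[1]:
        raise ValueError("streams must share width d")
    La = Xa.values.shape[0]
    joint = ModalFeatureMatrix(
        np.concatenate([Xa.values, Xb.values], axis=0),
        np.concatenate([Xa.mask, Xb.mask]), "joint")
    if not joint.mask.any():
        raise FusionInputError("combined stream has no unmasked positions")
    out = masked_self_attention(joint, p)
    Ha, Hb = out.H[:La], out.H[La:]
    if return_attention:
        return Ha, Hb, out
    return Ha, Hb


def _masked_maxpool(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.max(np.where(mask[:, None], values, -np.inf), axis=0)


def hmsa_fuse(X_smiles: ModalFeatureMatrix, X_graph: ModalFeatureMatrix,
              X_seq: ModalFeatureMatrix, X_mer: ModalFeatureMatrix,
              p_level1_drug: AttentionParams,
              p_level1_protein: AttentionParams,
              p_level2: AttentionParams
              ) -> tuple[PooledFeatures, FusionBundle]:
    """Two-level hierarchical fusion of the four modality streams.

    Level 1 fuses (SMILES, graph) and (sequence, 2-mer) separately with
    independent parameter sets; level 2 fuses the concatenation of the
    two level-1 outputs.  The level-2 output is split at the original
    boundaries into D_*, added to the residual encoder outputs X_* and
    max-pooled over valid positions.
    """
    mods = (X_smiles, X_graph, X_seq, X_mer)
    for X in mods:
        if X.values.shape[0] == 0 or not X.mask.any():
            raise FusionInputError("every modality needs >=1 unmasked position")
    Hs, Hg = hmsa_level(X_smiles, X_graph, p_level1_drug)
    Hq, Hm = hmsa_level(X_seq, X_mer, p_level1_protein)
    drug = ModalFeatureMatrix(np.concatenate([Hs, Hg], axis=0),
                              np.concatenate([X_smiles.mask, X_graph.mask]))
    prot = ModalFeatureMatrix(np.concatenate([Hq, Hm], axis=0),
                              np.concatenate([X_seq.mask, X_mer.mask]))
    H2a, H2b = hmsa_level(drug, prot, p_level2)
    Ls = X_smiles.values.shape[0]
    Lq = X_seq.values.shape[0]
    bundle = FusionBundle(H2a[:Ls], H2a[Ls:], H2b[:Lq], H2b[Lq:])
    pooled = PooledFeatures(
        _masked_maxpool(bundle.D_smiles + X_smiles.values, X_smiles.mask),
        _masked_maxpool(bundle.D_graph + X_graph.values, X_graph.mask),
        _masked_maxpool(bundle.D_seq + X_seq.values, X_seq.mask),
        _masked_maxpool(bundle.D_mer + X_mer.values, X_mer.mask),
    )
    return pooled, bundle


def export_attention(A: np.ndarray, path: str) -> None:
    """Write an attention matrix as TSV (query index, key index, weight)."""
    with open(path, "w") as fh:
        fh.write("query\tkey\tweight\n")
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                fh.write(f"{i}\t{j}\t{A[i, j]:.10g}\n")


# ------------------------------------------------- Tensor-level fusion


def fuse_streams_tensor(Xs: Tensor, Xg: Tensor, Xq: Tensor, Xm: Tensor,
                        masks: tuple[np.ndarray, np.ndarray,
                                     np.ndarray, np.ndarray],
                        w1_drug: AttentionWeights,
                        w1_prot: AttentionWeights,
                        w2: AttentionWeights,
                        mode: str = "hmsa") -> tuple[Tensor, ...]:
    """Batched fusion for training: inputs (B, L_*, d) -> four (B, d) Z's.

    ``mode`` selects the fusion strategy: ``hmsa`` (two-level joint
    self-attention), ``concat`` (no interaction; residual-only pooling)
    or ``cross_attention`` (two-level pairwise cross-attention baseline).
    """
    ms, mg, mq, mm = masks

    def pool(D: Tensor, X: Tensor, mask: np.ndarray) -> Tensor:
        return ad.where_mask(mask, D + X, -1e30).max(axis=-2)

    if mode == "concat":
        return (pool(Xs * 0.0, Xs, ms),
                pool(Xg * 0.0, Xg, mg),
                pool(Xq * 0.0, Xq, mq),
                pool(Xm * 0.0, Xm, mm))

    if mode == "cross_attention":
        Hs, _ = attention_core(Xs, Xg, w1_drug, ms, mg)
        Hg, _ = attention_core(Xg, Xs, w1_drug, mg, ms)
        Hq, _ = attention_core(Xq, Xm, w1_prot, mq, mm)
        Hm, _ = attention_core(Xm, Xq, w1_prot, mm, mq)
        prot = ad.concat([Hq, Hm], axis=-2)
        drug = ad.concat([Hs, Hg], axis=-2)
        mprot = np.concatenate([mq, mm], axis=-1)
        mdrug = np.concatenate([ms, mg], axis=-1)
        Ds, _ = attention_core(Hs, prot, w2, ms, mprot)
        Dg, _ = attention_core(Hg, prot, w2, mg, mprot)
        Dq, _ = attention_core(Hq, drug, w2, mq, mdrug)
        Dm, _ = attention_core(Hm, drug, w2, mm, mdrug)
        return (pool(Ds, Xs, ms), pool(Dg, Xg, mg),
                pool(Dq, Xq, mq), pool(Dm, Xm, mm))

    if mode != "hmsa":
        raise ValueError(f"unknown fusion mode {mode!r}")

    Ls, Lg, Lq = Xs.shape[-2], Xg.shape[-2], Xq.shape[-2]
    drug_in = ad.concat([Xs, Xg], axis=-2)
    mdrug = np.concatenate([ms, mg], axis=-1)
    prot_in = ad.concat([Xq, Xm], axis=-2)
    mprot = np.concatenate([mq, mm], axis=-1)
    H1d, _ = attention_core(drug_in, drug_in, w1_drug, mdrug, mdrug)
    H1p, _ = attention_core(prot_in, prot_in, w1_prot, mprot, mprot)
    joint = ad.concat([H1d, H1p], axis=-2)
    mjoint = np.concatenate([mdrug, mprot], axis=-1)
    H2, _ = attention_core(joint, joint, w2, mjoint, mjoint)
    nd = Xs.ndim
    sl = [slice(None)] * nd
    def seg(lo, hi):
        s = list(sl); s[-2] = slice(lo, hi); return H2[tuple(s)]
    Ds = seg(0, Ls)
    Dg = seg(Ls, Ls + Lg)
    Dq = seg(Ls + Lg, Ls + Lg + Lq)
    Dm = seg(Ls + Lg + Lq, H2.shape[-2])
    return (pool(Ds, Xs, ms), pool(Dg, Xg, mg),
            pool(Dq, Xq, mq), pool(Dm, Xm, mm))
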