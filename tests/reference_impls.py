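"""Independent brute-force reference implementations used as test oracles.

Deliberately written as plain nested loops over scalars/rows, with no
code shared with the package's vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np


def ref_attention(Xq: np.ndarray, Xkv: np.ndarray,
                  W_Q, W_K, W_V, b_Q, b_K, b_V,
                  q_mask=None, k_mask=None):
    """Scalar double-loop scaled dot-product attention with masking."""
    Lq, Lk = Xq.shape[0], Xkv.shape[0]
    d_att = W_Q.shape[1]
    if q_mask is None:
        q_mask = np.ones(Lq, dtype=bool)
    if k_mask is None:
        k_mask = np.ones(Lk, dtype=bool)
    Q = np.array([Xq[i] @ W_Q + b_Q for i in range(Lq)])
    K = np.array([Xkv[j] @ W_K + b_K for j in range(Lk)])
    V = np.array([Xkv[j] @ W_V + b_V for j in range(Lk)])
    A = np.zeros((Lq, Lk))
    H = np.zeros((Lq, d_att))
    for i in range(Lq):
        if not q_mask[i]:
            continue
        logits = []
        for j in range(Lk):
            if k_mask[j]:
                logits.append((j, float(Q[i] @ K[j]) / math.sqrt(d_att)))
        mx = max(v for _, v in logits)
        denom = sum(math.exp(v - mx) for _, v in logits)
        for j, v in logits:
            A[i, j] = math.exp(v - mx) / denom
        for j in range(Lk):
            H[i] += A[i, j] * V[j]
    return H, A


def ref_dmpnn(atom_feats, edges, bond_feats, W_b, W_x, W_f, b_f,
              W_alpha, b_alpha, T, message_fn="mean"):
    """Nested-loop directed message passing.

    ``edges``: list of (src, dst) directed pairs, one entry per directed
    edge; ``bond_feats[i]`` belongs to edges[i].  Messages to edge (v, w)
    sum over incoming edges (k, v) with k != w.
    """
    n = atom_feats.shape[0]
    h = {}
    for i, (v, w) in enumerate(edges):
        h[(v, w)] = np.maximum(
            np.concatenate([atom_feats[v], bond_feats[i]]) @ W_b, 0.0)
    P = {v: atom_feats[v] @ W_x for v in range(n)}
    for _ in range(T):
        m = {}
        for (v, w) in h:
            acc = np.zeros(W_b.shape[1])
            for (k, v2) in h:
                if v2 == v and k != w:
                    if message_fn == "mean":
                        acc = acc + (P[v] + P[k] + h[(k, v)]) / 3.0
                    else:
                        acc = acc + h[(k, v)]
            m[(v, w)] = acc
        h = {e: np.maximum(np.concatenate([h[e], m[e]]) @ W_f + b_f, 0.0)
             for e in h}
    out = np.zeros((n, W_alpha.shape[1]))
    for v in range(n):
        mv = np.zeros(W_b.shape[1])
        for (k, v2) in h:
            if v2 == v:
                mv = mv + h[(k, v2)]
        out[v] = np.maximum(
            np.concatenate([atom_feats[v], mv]) @ W_alpha + b_alpha, 0.0)
    return out


def ref_auc(labels, scores) -> float:
    """Pairwise concordance AUC; ties count half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    if not pos or not neg:
        return math.nan
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ref_average_precision(labels, scores) -> float:
    """Step-function area under the precision-recall curve.

    AP = sum over positives, in descending-score order, of
    precision-at-that-cut times the recall increment.
    """
    labels = list(labels)
    scores = list(scores)
    n_pos = sum(labels)
    if n_pos == 0:
        return math.nan
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    # group ties: sklearn computes precision/recall at distinct thresholds
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]]
            fp += 1 - labels[order[j]]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
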