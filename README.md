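# dtifuse

Drug–target interaction (DTI) prediction with multimodal encoders and
hierarchical multimodal self-attention fusion.

Virtual screening needs models that decide, from a molecule and a
protein sequence alone, whether the pair interacts. Single
representations miss structure: a SMILES string sees a molecule as text,
a molecular graph sees its topology; a raw residue sequence carries
global composition, its k-mer stream local context. `dtifuse` encodes a
drug twice (SMILES tokens through an embedding + CNN block; the
heavy-atom molecular graph through a directed message-passing network
whose readout is deliberately removed so per-atom features survive) and
a protein twice (residue tokens and 2-mer tokens, each through an
embedding + CNN block), then fuses the four token streams and classifies
the pair.

## The fusion mechanism

Plain cross-attention between modalities computes
H = softmax(QKᵀ/√d_k)·V, so each output row is a weighted combination of
the value rows — a linear transform of the key/value modality only; the
query modality's content never reaches the output. Hierarchical
multimodal self-attention instead stacks two streams into one token
sequence X = [X_a; X_b] and self-attends over the joint stream:

    Q = XW_Q + b_Q,  K = XW_K + b_K,  V = XW_V + b_V
    A = softmax(QKᵀ/√d_k)      — decomposes into intra- and inter-modal blocks
    H = A·V                     — mixes both value sets

Level 1 fuses (SMILES, graph) and (sequence, 2-mer); level 2 fuses the
concatenation of the two level-1 outputs. The output is split back at
the original segment boundaries, added residually to the encoder
outputs, and max-pooled per modality into four vectors Z_smiles,
Z_graph, Z_seq, Z_mer. A four-layer funnel classifier
(dropout + LeakyReLU after layers 1–3, sigmoid on the final logit) maps
their concatenation to an interaction probability, trained with binary
cross-entropy. Both the cross-attention baseline and a plain
concatenation baseline are available as fusion-mode switches for
ablations.

The differentiable layers run on a compact reverse-mode autodiff engine
over NumPy (`dtifuse.autodiff`), gradient-checked against finite
differences; RDKit handles molecule parsing and scikit-learn the
metrics. See `docs/methods.md` for the full model description and
design rationale.

## Worked example

Every stage runs on seeded synthetic data with a planted, learnable
rule: a pair interacts iff the drug contains a pyridine pharmacophore
AND the protein contains a fixed tetrapeptide motif. A non-neural
matching oracle scores AUC 1.0 on any emitted dataset, so the task is
solvable exactly from the inputs — what is being tested is whether the
pipeline learns it.

```python
from dtifuse.benchmark import run_planted_benchmark

m = run_planted_benchmark(seed=7)                        # ~1-2 min, one core
print("AUC", m.auc, "AUPR", m.aupr, "ACC", m.acc)
c = run_planted_benchmark(seed=7, shuffle_labels=True)   # negative control
print("shuffled AUC", c.auc)
```

prints

```
AUC 1.0 AUPR 1.0 ACC 0.98
shuffled AUC 0.4951923076923077
```

Trained for 15 epochs on 400 planted-rule pairs (d = 32, T = 2, k = 2),
the model ranks all 100 held-out pairs correctly (AUC/AUPR 1.0) and
misclassifies 2 of 100 at the 0.5 threshold. With training labels
shuffled, held-out AUC collapses to chance (≈0.5) — the skill comes from
the planted signal, not leakage.

The same pipeline is scriptable from the shell:

```sh
dtifuse simulate --seed 3 --n-pairs 500 --out data/
dtifuse train data/interactions.tsv --seed 3 --epochs 15 --out run/
dtifuse ablate data/interactions.tsv --epochs 10 --fusion hmsa --out ablation/
dtifuse rank data/interactions.tsv --checkpoint run/checkpoint \
        --anchor-smiles "CCOc1ccncc1" --top-n 20 --out ranking/
```

`simulate` emits a TSV (`smiles	sequence	label` + ids) with a JSON
manifest; `train` writes a checkpoint (`.npz` weights + JSON config
sidecar) and per-fold metrics; `rank` scores every candidate against the
anchor and writes the top-n table.

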