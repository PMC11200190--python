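# Methods

`dtifuse` predicts whether a small molecule interacts with a protein by
encoding each pair through four token streams, fusing them with a
two-level hierarchical multimodal self-attention, and classifying the
fused representation. This note records the model, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Inputs and featurization

A record is a (SMILES, protein sequence, label ∈ {0,1}) triple.

**SMILES tokens.** Characters map to integer ids 1..64 via a frozen
64-character label-encoding alphabet (`src/dtifuse/data/smiles_alphabet.txt`,
one symbol per line, file order = id order); id 0 is padding. Unknown
characters raise by default (`unk_policy="error"`); a lenient policy maps
them to the last id. Vectors are truncated/zero-padded to `L_smiles`
(default 150).

**Protein tokens.** Residues map to ids 1..22 (20 standard amino acids +
`U` + `X`, alphabetical, then `U`, `X`); any other character falls back
to `X`. Default cap `L_protein` = 1000.

**k-mer tokens.** A window of length k slides one residue at a time, so a
length-N sequence yields N−k+1 tokens. A k-mer (a₁…a_k) receives the
positional base-22 id Σⱼ (id(aⱼ)−1)·22^(k−j) + 1 — a bijection onto
[1, 22^k]. Vocabulary sizes: 22, 484, 10 648 for k = 1, 2, 3; k = 4
(234 256) is rejected by the default configuration because the embedding
table would dominate the parameter count. Default k = 2.

**Molecular graph.** RDKit parses the SMILES into a heavy-atom graph;
each chemical bond contributes two directed edges with an involutive
reverse-edge map. Atom features concatenate encodings of 8 properties:
atomic number (one-hot over B/C/N/O/F/Si/P/S/Cl/Br/I + other), total
degree 0–5, formal charge −2..+2, chirality tag, attached hydrogens 0–4,
hybridization (SP..SP3D2 + other), aromaticity flag, and atomic mass
scaled by 0.01 (40 dims). Bond features concatenate 4 properties: bond
type (single/double/triple/aromatic), bond position interpreted as
ring membership (the one standard positional bond attribute alongside
type/conjugation/stereo), conjugation flag, and stereo one-hot (12 dims).
Hydrogens are not nodes; they appear only through the H-count feature.

## Encoders

All four modalities share one model width d (default 64; the desk-scale
benchmark uses 32). Sharing one width is required by the residual
addition and the level-2 concatenation in the fusion stage.

**Token streams** pass through an embedding table (padding row pinned to
zero and excluded from updates) and a stack of same-padding 1-D
convolutions with ReLU — default 3 layers, kernel sizes (3, 5, 7), all
channels d. Spatial length is preserved so every token keeps a feature
row; masked positions are re-zeroed after every layer. The CNN shape is
an experiment knob, not part of the method's identity.

**Molecular graphs** are encoded by a directed message-passing network
with hidden states on directed bonds. Edge initialisation:
h⁰_{vw} = ReLU(W_b·[x_v ; e_{vw}]). For T rounds (default T = 2 — deeper
stacks over-smooth node states), the message to edge v→w sums over
incoming neighbours k ∈ N(v)\{w}, excluding the reverse edge to prevent
immediate back-flow; the update is a single shared fully connected layer
on [hᵗ ; m^{t+1}] followed by ReLU. Two message functions are provided:

* `mean` (default): M = elementwise mean of (W_x·x_v, W_x·x_k, h_{kv}),
  with W_x a shared projection of raw atom features to width d. The raw
  atom/edge vectors have different widths, so averaging is only defined
  after projection; projecting, rather than averaging raw features, is a
  pinned choice.
* `edge_hidden_sum`: the classical convention, M = h_{kv}.

After T rounds, per-atom features are h_v = ReLU(W_α·[x_v ; Σ_k h^T_{kv}]).
**No readout/pooling is applied**: atoms enter fusion as tokens, which is
what lets the attention stage see intra-molecular structure.

## Fusion

**Cross-attention** (ablation baseline) takes queries from one stream and
keys/values from another: H = softmax(QKᵀ/√d_k)·V. Every output row is a
convex combination of V's rows, so H is confined to the row span of a
linear transform of the key/value modality — it cannot carry query-side
features forward. This limitation is verified numerically in the tests.

**Hierarchical multimodal self-attention** stacks two streams into one
token sequence and applies scaled dot-product self-attention to the
joint stream. The attention matrix then decomposes into the four
intra-/inter-modal blocks, and outputs mix both value sets. Level 1
fuses (SMILES, graph) and (sequence, 2-mer) with separate parameter
sets (sharing is not required by anything and separate sets are the
conservative reading); level 2 applies the same construction to the
concatenation of the two level-1 outputs, i.e. the four segments in
order smiles|graph|seq|mer. The level-2 output is split at the original
boundaries into D_*, added to the residual encoder outputs X_* (the
inputs to fusion, not the embeddings — hence d_att = d), and max-pooled
over valid positions only into four Z vectors.

Padding: masked keys get −∞ logits (exactly zero attention mass); masked
query rows output zeros. Attention is single-head by default, faithful
to the block decomposition above; head count is configurable. No layer
norm or feed-forward sublayer is inserted — nothing in the mechanism's
definition calls for them, and fidelity beats transformer convention.

## Classifier and loss

The four Z vectors are concatenated (width 4d) and passed through four
fully connected layers. Dropout (default rate 0.1) and LeakyReLU follow
layers 1–3 only: an activation after the final linear layer would break
the logit, which a sigmoid maps to (0,1). Hidden widths default to
(1024, 512, 256), scaled to (8d, 4d, 2d) when d ≤ 32 so desk runs keep a
proportionate funnel. Loss is binary cross-entropy with probabilities
clipped to [1e−7, 1−1e−7]; the literal summed form is exposed and
tested, the mean form is the training default for step-size stability.

## Numerical core

The differentiable layers run on a compact reverse-mode autodiff engine
over NumPy (`dtifuse.autodiff`): dense/batched matmul, pointwise
nonlinearities, reductions, gather/scatter (graph message passing and
embedding lookup), masked softmax and same-padding conv1d, each with an
analytic vector-Jacobian product verified against central finite
differences in the test suite. The trainable model runs in float32; the
functional single-sample API and all oracle comparisons run in float64.
Graphs in a batch are processed as one disjoint union and scattered back
into a padded (batch, atoms, d) layout. Max-pool ties route gradient to
the first argmax. Optimisation is Adam; the default learning rate is
1e-3, the conventional Adam setting for models of this size — at the
short desk-scale budgets used here smaller rates leave the model
essentially at initialisation.

## Training and evaluation protocol

`make_splits(n, seed)` holds out a fixed 10% (rounded) test set, then
partitions the remaining pool into 10 folds; each fold trains on nine
tenths and validates on one tenth. The test set never intersects any
fold. Training runs minibatch Adam (default 150 epochs, batch 50);
after each epoch the model is scored on the validation set and the
parameters of the best validation-AUC epoch are kept ("best-performing"
is realised as AUC since no criterion is pinned elsewhere). Metrics:
rank-based ROC AUC, step-function average precision (AUPR), and
accuracy/precision/recall at a configurable threshold (default 0.5 — the
natural cut for a balanced BCE classifier). Single-class label sets
flag the ranking metrics as undefined rather than guessing. No
resampling or class weighting is applied in unbalanced mode by default;
an optional positive-class weight exists. Candidate ranking scores
(anchor, candidate) pairs and returns the top-n by descending
probability with stable ties.

## Synthetic benchmark

The generator emulates benchmark-style DTI inputs with a planted,
learnable rule. Molecules are assembled from a fragment grammar (alkyl
chains, carbocycles, benzene, O/N/S substituents, carbonyls) closed
under linear concatenation, so every emitted SMILES parses; about half
carry a pyridine ring — the pharmacophore — which is the grammar's only
source of aromatic nitrogen, making it visible both as the `n` token in
SMILES and as a substructure in the graph. Proteins are i.i.d. draws
from the 20 standard amino acids (never `U`/`X`, so the fallback path is
exercised only deliberately); about half carry a fixed tetrapeptide
motif (`HWCY`) written at a random position — detectable by small CNN
receptive fields and within two message-passing rounds. A pair is
positive iff pharmacophore AND motif are present. Pairs are sampled
without duplication to hit the requested positive fraction (0.5 by
default; 1/11 mirrors a 1:10 unbalanced design). Labels are noiseless by
default; a flip-rate option exists. A non-neural rule-matching oracle
achieves AUC 1.0 on any emitted dataset — the certificate that the task
is solvable from the inputs.

Defaults: 80 drugs x 80 proteins, 500 pairs, protein lengths 50–200,
molecule sizes 3–25 heavy atoms.

**What passing shows.** The desk-scale benchmark (400 train / 100 test,
d = 32, T = 2, k = 2, ≤ 15 epochs, one CPU core) demonstrates that the
full pipeline — featurization, encoders, fusion, classifier, training
loop — can extract a conjunctive signal that is present in all four
modalities, and the label-shuffled control (training labels permuted,
test labels intact) confirms the skill comes from that signal, not
leakage. The ablation sweep (5 seeds, matched 10-epoch budget) checks
the fusion mechanism is never materially worse than plain concatenation
on learnable data. **What it does not show:** real binding physics,
property-matched decoys, cross-target generalisation, or the margins
between fusion strategies on real benchmarks — the planted rule is easy
enough that all fusion modes saturate near AUC 1.0.

## Degenerate inputs and tie-breaks

Empty sequences, sub-k sequences and unparseable SMILES raise typed
errors; during batch prediction such records go to a rejects report
while the rest are scored. A 2-atom molecule passes zero messages at
every D-MPNN step (the neighbour set excludes the reverse edge); an
isolated atom gets h_v = ReLU(W_α·[x_v ; 0]). Attention over a stream
with zero unmasked positions is rejected, as is max-pooling an empty
modality. Ranking ties break by input order. NaN training loss aborts
with the offending batch indices.

## Known limitations

* CPU-only, single-core numerics; problem sizes beyond a few thousand
  pairs per epoch become slow.
* The 22-residue and 64-character alphabets are self-consistent frozen
  choices; token ids are not interchangeable with other implementations.
* Multi-head attention is provided but untested beyond shape contracts;
  the defaults are single-head.
* The unbalanced mode changes only the label ratio; it does not model
  the covariate shift of real unbalanced screens.
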