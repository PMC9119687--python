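# drugraph

Graph neural networks for predicting whether a kinase inhibitor kills a
cancer cell line (cytotoxic response) or merely arrests its growth
(cytostatic response), from multi-omics data integrated on the human
protein–protein interaction network.

## The problem and the approach

A (cell line, drug) pair is represented as a single annotated graph:

- **nodes** are proteins from a confidence-filtered PPI network
  (STRING-style combined score ≥ 500);
- **node annotations** are the cell line's differential gene expression
  category (up / down / normal), disease–gene association scores for the
  cell line's disease (DISEASE scale 1–10, DisGeNET scale 0.01–1), the
  drug's kinase-inhibition potency pIC50 = −log₁₀ IC50 when it passes the
  6.3 threshold (≙ IC50 ≤ 500 nM), and a kinase flag;
- **the label** is the sign of the growth-rate inhibition extremum GRmax:
  negative → cytotoxic (positive class), positive → cytostatic. Records
  with infinite or multiply-reported GR50 are discarded.

Because most non-kinase proteins carry no information, graphs are first
**reduced**: connected groups of non-kinase proteins with identical
expression category and the same biological-process (GO-derived) cluster are
merged into virtual nodes whose annotations and edge weights are medians
over the group. This shrinks the graph while enriching the kinase fraction.

The classifier is a three-block graph network. Each block propagates with a
feature-space attention matrix Γ,

```
γ_ij = exp(β cos(x_i, x_j)) / Σ_{k ∈ N(i) ∪ {i}} exp(β cos(x_i, x_k)),
```

(row-stochastic over the closed neighborhood, β trainable), then applies a
GIN-style update `X' = Θ(ΓX + (1 + ε)X)` with a trainable two-layer Θ and
scalar ε. Setting `attention_enabled=False` replaces Γ with the classical
symmetric-normalized operator `D^{-1/2} A D^{-1/2}` (equal propagation).
Per-block embeddings are aggregated by jumping-knowledge element-wise
max-pooling, read out by a permutation-invariant Set2Set layer (iterated
LSTM attention), and classified by a fully connected head. Evaluation is
leave-one-tissue-out cross-validation, so no cell line or tissue is shared
between training and validation.

The model (including a compact reverse-mode autodiff core) is implemented in
pure numpy; no deep-learning framework is required.

## Worked example

`examples/01_worked_example.py` runs the 13-node subnetwork (4 kinases,
9 non-kinases) of a breast-adenocarcinoma cell line paired with the dual
SRC/ABL-family inhibitor dasatinib:

```
input graph: 13 nodes, 15 edges, label=1 (1 = cytotoxic)
reduced graph: 9 nodes, 10 edges
  virtual node from members ('a', 'b'): dge=up, disease association=None
  virtual node from members ('c', 'e'): dge=normal, disease association=1.3
  virtual node from members ('d', 'f', 'g'): dge=down, disease association=1.9
node reduction: 30.8%  kinase fraction: 0.31 -> 0.44
```

The three merged groups are exactly the connected non-kinase sets sharing an
expression category and a process cluster; the virtual associations are
medians over members (absent values enter as 0).

`examples/03_train_and_evaluate.py` trains on a synthetic planted-signal
benchmark (instances are cytotoxic when the drug inhibits up-regulated,
disease-associated kinases) and evaluates on a held-out tissue:

```
137 training / 43 validation graphs (held-out tissue: breast tissue)
final training loss 0.282
held-out tissue AUC 0.820, balanced accuracy 0.868, precision 0.769, recall 0.833, F 0.800
```

An AUC well above 0.5 on an unseen tissue means the network recovered the
planted mechanism rather than memorizing cell lines. The other examples
cover table simulation/dataset building and full tissue-level
cross-validation. A thin CLI (`drugraph simulate|build|reduce|predict|cv`)
wraps the same functions.

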