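# Methods

## Graph construction

The base network is built from a STRING-style edge table; the confidence
threshold (default 500 on the 0–1000 scale) is inclusive, reversed/duplicate
pairs collapse to the maximum score, self-pairs are dropped. The *full*
filtered network is carried into every instance — the reduction step, not an
induced subgraph, is what shrinks it — so reduction statistics refer to the
whole network.

Annotation is per (cell line, drug): expression categories come from the
cell line's differential-expression rows (genes without a row default to
`normal`, matching the convention that curated sources list regulated genes
explicitly); association scores are looked up through a user-supplied
cell-line → disease mapping and kept as two separate features (one per
source database — the sources use incommensurate scales and no published
rule combines them); inhibition potencies below the pIC50 threshold
(default −log₁₀(500·10⁻⁹) ≈ 6.3) are treated as absent, and when a
kinase–drug pair has several retained measurements the maximum is used
(the most potent reported inhibition). The kinase universe is the set of
kinases appearing anywhere in the profiling table, on the reasoning that
kinome panels cover the kinome; there is no separate kinase list input.

Labels follow the sign of GRmax (negative → cytotoxic, label 1). GRmax = 0
is assigned the cytostatic class, since only negative values indicate net
cell kill. Pairs with infinite GR50 or more than one GR50 record are
rejected with a per-pair reason in the build report.

### Feature encoding

Each node becomes a 7-vector: one-hot expression (up, down, normal),
disease-association / 10, DisGeNET association (already in [0,1]),
pIC50 / 10, kinase flag. The one-hot block guarantees no all-zero row, which
keeps the cosine similarities of the attention well defined at the input
layer; absent annotations map to 0 ("no useful information").

## Graph reduction

Merge eligibility is: both endpoints non-kinase **and** identical expression
category **and** identical biological-process cluster. Merge groups are the
connected components of the eligibility subgraph, hence maximal and
deterministic. "Similar expression" is operationalized as exact categorical
equality because the expression input is categorical. Only non-kinases
merge: merging is what raises the kinase fraction, and kinase nodes carry
the information the classifier needs. A node without a cluster assignment is
its own singleton cluster (logged once).

Virtual-node annotations and collapsed parallel-edge weights are medians
over the group (absent values enter as 0; the median of an even-cardinality
multiset is the mean of the two middle values). A median taken over absent
values can fall below a source database's minimum (e.g. median of
{0, 2.6} = 1.3 on the 1–10 scale), so range validation applies to original
nodes only; virtual nodes accept [0, max]. Reduction is single-pass and
virtual nodes never re-merge — components are already maximal, so a second
pass is a no-op (verified by an idempotence test).

## The network

Three convolution blocks (a fourth adds nothing once the information horizon
covers the graph diameter), each: attention propagation followed by a
GIN-style update

    X' = Θ(ΓX + (1 + ε)X)

with Θ a linear–ReLU–linear transform to the common hidden width and ε a
trainable scalar — the GIN update with the attention operator substituted
for its usual sum-aggregation. The attention operates purely in feature space — edge
confidence weights never enter Γ; adjacency only defines neighborhoods.
Cosine against a zero row is defined as 0 through an additive floor of 1e-12
in the norms. With `attention_enabled=False` the propagation is
`D^{-1/2} A D^{-1/2}` with isolated nodes passing through unchanged (the
operator would otherwise zero them).

Per-block outputs (all at the hidden width, so the pool is well defined) are
combined by element-wise max (jumping knowledge); the readout is Set2Set
with dot-product attention and 3 steps (readout steps and all sizes are
package defaults); the head is one
hidden fully-connected layer with dropout and a 2-way softmax trained with
cross-entropy.

Because no deep-learning framework is assumed, the package carries a small
reverse-mode autodiff core over float64 numpy arrays (broadcast arithmetic,
matmul, pointwise nonlinearities, gather/segment-sum for message passing,
fused softmax cross-entropy) and an Adam optimizer. The backward sweep frees
the operation graph as it goes, keeping memory flat over long trainings.
Everything is single-threaded and bit-reproducible for a fixed seed. The
trainable batched path and the dense single-graph reference operations
(`attention_matrix`, `equal_propagation`, `conv_block_forward`,
`jk_max_pool`, `set2set_readout`) implement the same mathematics and are
cross-checked in the tests.

### Training defaults

hidden width 16, classifier width 32, dropout 0.1, Adam at 1e-2 with cosine
decay to a tenth over 60 epochs, batch size 32, decision threshold 0.5.
These were chosen for reliable convergence on the synthetic benchmark across
initialization seeds; they are not claims about any external dataset.

## Evaluation protocol

Leave-one-tissue-out: one fold per distinct tissue group (ordered by name),
every instance of the held-out tissue in validation, so no cell line — and
no tissue — appears on both sides. Fold assignment is independent of the
model seed; each fold trains from scratch with a fold-derived seed. Metrics:
rank-statistic AUC with ties counted ½ (scikit-learn), precision, recall,
balanced accuracy (mean per-class recall), F measure at threshold 0.5.
One-class validation sets get `auc=None` with a reason while the threshold
metrics are still reported, so a degenerate fold does not abort a run.
Both per-fold ROC tables and a pooled ROC over all validation scores are
emitted, since either aggregation convention is found in practice.

## Synthetic data

The generator emulates the structure the method assumes, at desk scale:

- **scaffold**: connected preferential-attachment graph, 150 genes,
  attachment degree 2, 2% kinases (the regime in which reduction visibly
  enriches kinase density); confidences uniform in [500, 1000] with an
  optional sub-threshold fraction to exercise the filter;
- **clusters**: breadth-first assignment in which each gene copies a
  neighbor's cluster with probability 0.7 (12 clusters) — spatial coherence
  is what gives the reduction connected mergeable groups;
- **profiles**: 50 cell lines in 5 tissues (10 each), one disease term per
  tissue; expression up/down rates 0.25/0.15 per gene; association presence
  0.8 for kinases and 0.3 otherwise (kinase oncogenes are
  disproportionately disease-annotated), scores uniform on each source
  scale; 10 drugs each inhibiting ~60% of the kinome with pIC50 uniform in
  [6.3, 10], every drug inhibiting at least one kinase and every kinase
  appearing in the panel;
- **labels**: with s = number of kinases simultaneously up-regulated,
  inhibited by the drug and disease-associated above 0.2 (normalized),
  the instance is cytotoxic with probability σ(12·s − 6) — effectively a
  step at s ≥ 1 — then flipped with probability 0.05; |GRmax| is uniform,
  GR50 log-normal with a 5% infinite fraction to exercise filtering.
  Ground truth (s, the clean and noisy labels) is retained for diagnostics.

The steep sigmoid matters: a shallower rule would itself inject label
randomness beyond the stated 5% noise and cap the recoverable AUC below
what the noise alone implies. With these defaults the dataset has ~475
accepted instances, ~32% positive, and the ground-truth signal itself
scores ≈ 0.97 held-out AUC — the effective ceiling any model can reach.

One identifiability caveat follows from the small scale: with three kinases
and five diseases, a kinase whose disease-association indicator happens to
be constant across the training tissues leaves the labeling rule
under-determined — a model can attribute its effect to kinase identity
instead of the association feature and then misrank the held-out tissue
where that indicator flips. Single-fold results at unlucky dataset seeds
reflect this; tissue-averaged (full leave-one-tissue-out) results are the
representative quantity and are what the reproduction script reports.

What the generator does **not** model: real expression distributions or
assay noise, score semantics of the confidence scale, identifier aliasing,
correlated inhibition profiles across chemically similar drugs, or
tissue-specific network rewiring. Passing the recovery benchmark therefore
shows the pipeline and model can extract a planted graph-and-feature
mechanism under grouped validation — not that any particular external
dataset would reach the same numbers.

## Known limitations

- The attention's cosine is computed on current-layer features; after ReLU
  transforms, exactly-zero embedding rows are possible in principle and are
  handled by the norm floor (cosine 0), not excluded.
- Mini-batch training collates graphs into one disjoint union; very large
  graphs are processed whole (no neighbor sampling).
- The serialization container stores node/edge tables as TSV inside an
  uncompressed ZIP; it is meant for inspectability, not throughput.
- `GRRecord` keeps one representative row per pair plus the count of
  reported GR50 values; distinct GRmax values under a duplicated pair are
  rejected rather than reconciled.
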