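# Methods

`hganlda` predicts lncRNA–disease associations (LDA) with a hierarchical
graph attention network over metapath subgraphs of a ternary
lncRNA–miRNA–disease graph. This note documents the model, its
assumptions, the parameters that matter, the synthetic benchmark, and
the numerical/design choices that were genuinely open.

## Node similarities and features

* **Sequence similarity (LSS).** For lncRNAs `i, j`,
  `LSS(i,j) = 1 − dist(i,j) / (len_i + len_j)`, where `dist` is a
  weighted edit distance with substitution cost 2 and insertion/deletion
  cost 1 (so a substitution is never cheaper than a delete+insert).
  Characters outside `{A,C,G,T,U}` are kept as ordinary symbols and only
  warned about. A pair of two distinct empty sequences has a zero
  denominator and is rejected; the self-similarity of an empty sequence
  is defined as 1 so one empty record does not invalidate a matrix.
* **Disease semantic similarity (DSS).** Wang-style similarity on a
  child→parent disease ontology DAG. The contribution of ancestor `t`
  to disease `D` is `0.5^k` with `k` the shortest ancestor-path length
  (the max over paths of a constant per-edge decay is the decay at the
  shortest path, computed by BFS). `DSS(i,j)` is the summed shared
  contribution over `T(i) ∩ T(j)` divided by `DV(i) + DV(j)`. The decay
  0.5 is fixed, not exposed.
* **GIP kernel (LGS/DGS).** `exp(−ξ‖profile_i − profile_j‖²)` on binary
  association profiles (rows of the lncRNA–disease matrix for lncRNAs,
  columns for diseases), with bandwidth `ξ = 1 / mean‖profile‖²`. An
  all-zero association matrix leaves ξ undefined and is rejected.
* **Fusion.** `LSM = (α·LSS + (1−α)·LGS)/2` and likewise `DSM` with
  DSS/DGS. α defaults to 0.5 (neutral, no guidance for a better value)
  and the divisor 2 is kept literally even though it caps fused values
  at 0.5 — a uniform scale absorbed by the learned projection. Node
  features are the raw rows of LSM / DSM (no normalisation — none is
  part of the reference design).

## Graphs

* **Metapath subgraphs.** L–D–L, L–M–L, D–L–D and D–M–D each induce a
  homogeneous adjacency: two endpoint nodes are joined when at least
  one intermediate node links to both, i.e. the binarised cross-product
  `E·Eᵀ` (or `Eᵀ·E`). Multiple shared intermediates still give one
  binary edge. Every node receives a self-loop so the attention softmax
  is defined for isolated nodes.
* **KNN homogeneous graphs.** Each node selects itself plus its `k−1`
  most similar peers under the fused similarity (default `k=20`,
  clipped to the node count); ties at the cut break by ascending index
  for determinism; the directed selection is symmetrised by union.

## Hierarchical attention model

Per node type (lncRNA / disease):

1. features are projected into a shared 64-dimensional space;
2. on each subgraph, per head `h`, `S = H·W_h`, neighbour logits
   `φ_uv = LeakyReLU(S_u·S_v)` (slope 0.2) are softmax-normalised over
   `u`'s neighbour set, neighbours aggregated, ELU applied, and the
   (default 4) heads averaged. Each head owns its projection `W_h`
   (64→128); identical heads provably reduce to a single head;
3. metapath-level attention scores each subgraph with
   `mean_u q·tanh(W_G Z_u + b)` (semantic dimension 128), softmaxes
   across subgraph types, and mixes the subgraph embeddings. The
   lncRNA branch fuses {LDL, LML}, the disease branch {DLD, DMD};
   parameters are separate per node type and per branch;
4. the KNN graph passes through the same node-level attention
   (separate parameters); heterogeneous and homogeneous embeddings are
   concatenated per node (`branch_combine="sum"` is available);
5. the prediction head maps the two pair embeddings through learned
   linear transforms, adds them, applies an ELU hidden layer (64
   units) and a sigmoid scalar. The hidden nonlinearity is essential:
   a purely additive score `σ(w·Z_l + w·Z_d + b)` ranks every lncRNA
   identically for every disease and cannot express block matching.
   Transform-then-add is algebraically identical to concatenating the
   pair and applying one linear layer, so no separate pair-level
   concat mode exists.

Ablations: `ablation_nho` drops step 4 (heterogeneous branch only);
`ablation_na` freezes the metapath weights at `1/GN` (uniform).

Training is full batch: mean binary cross-entropy (probabilities
clamped at 1e-12), Adam, learning rate 1e-3, at most 500 epochs,
weight decay 5e-3. Two numerical choices matter:

* **Decoupled weight decay.** Decay is applied as `p ← (1−lr·wd)·p`
  rather than added to the gradient. Under Adam's per-parameter
  normalisation a coupled L2 term moves every weight toward zero at
  roughly the learning rate regardless of how small the data gradient
  is; near initialisation the cross-entropy gradient is tiny (outputs
  sit at σ(0)=0.5) and the coupled form demonstrably collapses the
  whole network into the constant-output fixed point (loss pinned at
  ln 2) before anything is learned.
* **Stable masked softmax.** Neighbour logits are shifted by their
  per-row maximum (treated as a constant) before exponentiation.

Parameters use seeded uniform Glorot initialisation; biases start at
zero. No dropout or normalisation layers (none in the reference
design). All arithmetic is float64 numpy, so same-seed runs are
bit-reproducible. The autodiff engine is a small in-package
reverse-mode tape over dense arrays; its gradients are pinned down by
finite-difference tests.

## Cross-validation protocol

Known associations are shuffled and split into five folds. Per fold,
test positives are removed from the association matrix *before* GIP
kernels, fused features, metapath subgraphs and KNN graphs are rebuilt
(both behaviours are flags, default on), so no held-out edge leaks
into the graph structure — the reference protocol is silent here and
leak-free is the defensible default. Negatives are one uniform draw
from the zero entries, chunked in step with the positive folds, so
train and test negatives are balanced and disjoint; sampled negatives
are labels only and never become graph edges. Metrics: AUC, AUPR
(step-wise interpolation as in scikit-learn's average precision), and
accuracy / precision / recall / F1 at threshold 0.5 (configurable;
the reference threshold is unstated). Folds are averaged unweighted.

The case-study ranking removes one query disease's known links, trains
on the remaining positives plus equal negatives (never sampled from
the query column), scores every lncRNA against the query and returns
the top 15 by descending score.

## Synthetic benchmark

The generator emulates the statistical structure the model exploits,
with all randomness derived from a single seed:

* lncRNAs, diseases and miRNAs share one round-robin block partition
  (defaults: 120/80/60 nodes, 6 blocks);
* association matrices are Bernoulli with `p_in=0.3` inside matched
  blocks and `p_out=0.02` elsewhere (per-matrix overrides exist so
  real datasets' very different sparsities can be emulated); a repair
  step gives isolated nodes one within-block edge;
* sequences (100–180 nt, RNA alphabet) descend from per-block ancestor
  sequences with 5% per-base substitution — within-block sequence
  identity is then ~90%, a plausible "sequence family" regime;
* the ontology is a random rooted tree whose block members attach
  under a shared block root (branching cap 3), so block-mates share
  close ancestors.

A `scramble_associations` control permutes all entries of every
association matrix uniformly: density is preserved, planted structure
destroyed, and any leakage in the pipeline would show up as
above-chance AUC. (A mere relabelling of blocks would not work as a
control — the planted distribution is invariant under consistent
relabelling.)

What the generator does **not** emulate: degree heterogeneity
(hub lncRNAs/diseases), overlapping or hierarchical communities,
RNA secondary structure, and real MeSH topology. Passing the benchmark
therefore shows the pipeline recovers clean block structure without
leakage; it does not certify performance on curated databases.

### The recovery ceiling

Under these conditions a held-out pair inside a matched block is
conditionally i.i.d. given the block structure, so the Bayes-optimal
score is effectively binary (matched vs unmatched). With balanced
negatives, `P(matched | positive) = 0.75` and
`P(matched | negative) = 0.125`, giving a ceiling of

    AUC* = 0.75·0.875 + ½·(0.75·0.125 + 0.25·0.875) ≈ 0.8125

and, by simulation with random tie-breaking, AUPR* ≈ 0.80. No method
can exceed this in expectation at these settings; benchmark numbers
should be read against the ceiling, not against 1.0.

### Desk-scale training schedule

The benchmark trains 200 epochs at learning rate 2.5e-3, conserving
the reference schedule's total step budget (500 epochs × 1e-3) at the
shorter run; at the reference rate the model is still escaping the
initial plateau when 200 epochs end. A single stability probe over
{1, 2.5, 5, 10}×1e-3 confirmed larger rates destabilise training.
Library defaults remain 500 epochs at 1e-3.

## Known limitations

* miRNA nodes act only as metapath connectors; the reference design
  defines no miRNA features or projections downstream, and none are
  invented here.
* Full-batch dense training is sized for hundreds-to-thousands of
  nodes per type; the engine has no sparse or GPU path.
* Whether GIP should be recomputed per fold is a genuine protocol
  ambiguity; the default recomputes (leak-free) and the flag
  `gip_per_fold=False` reproduces the leaky variant for comparison.
* The AUC an end-to-end run reports on synthetic data is bounded by
  the ceiling above; with the 200-epoch schedule the benchmark lands
  around 0.6–0.7 mean AUC (seed-dependent), the gap to the ceiling
  being remaining optimisation slack, not leakage — the scrambled
  control sits at chance.
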