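# hganlda

Hierarchical graph attention over metapath subgraphs for predicting
lncRNA–disease associations.

Most lncRNA–disease links are unverified, and wet-lab validation is
slow; computational ranking of candidate links narrows the search.
`hganlda` is aimed at computational biologists who have three binary
association tables (lncRNA–disease, lncRNA–miRNA, miRNA–disease),
lncRNA sequences and a disease ontology, and want a trained model that
scores unobserved lncRNA–disease pairs and ranks candidates for a
query disease.

## Model

Node features fuse two similarity views per node type:

* lncRNAs — weighted-edit-distance sequence similarity
  `LSS(i,j) = 1 − dist/(len_i+len_j)` (substitution 2, indel 1) and a
  Gaussian interaction-profile kernel
  `LGS(i,j) = exp(−ξ‖LD(i,:)−LD(j,:)‖²)`, fused as
  `LSM = (α·LSS + (1−α)·LGS)/2`;
* diseases — Wang semantic similarity on the ontology DAG (decay 0.5)
  and the column-profile GIP kernel, fused the same way into `DSM`.

From the ternary association graph, four metapaths (L–D–L, L–M–L,
D–L–D, D–M–D) induce homogeneous subgraphs (`E·Eᵀ` binarised, plus
self-loops); two more homogeneous graphs come from the k nearest
neighbours of the fused similarities. A two-level attention network —
per-subgraph multihead dot-product attention
`a_uv = softmax_v LeakyReLU(S_u·S_v)`, `Z_u = ELU(Σ_v a_uv S_v)`,
then metapath-level attention
`ω_G = softmax_G mean_u q·tanh(W_G Z_u + b)` — produces node
embeddings; a fully connected head scores each pair,
`y_ij = σ(w·ELU(W_l Z_li + W_d Z_dj + b₁) + b₂)`. Training is
full-batch Adam on balanced binary cross-entropy under five-fold
cross-validation, with held-out edges masked from every derived
quantity (GIP, features, subgraphs). The attention network runs on a
small in-package reverse-mode autodiff engine over numpy
(gradient-checked against finite differences).

See `docs/methods.md` for assumptions, parameter defaults, the
synthetic benchmark's recovery ceiling and the numerical choices.

## Worked example

Generate a planted-block synthetic dataset (120 lncRNAs, 80 diseases,
60 miRNAs in 6 shared blocks), then train and evaluate:

```
hganlda simulate --seed 0 --out data/
hganlda train --data-dir data/ --folds 5 --seed 0 --epochs 200 --out run/
hganlda rank --data-dir data/ --disease d007 --top 5 --epochs 200
```

A three-seed average of that five-fold run (library call
`hganlda.experiments.run_benchmark(seeds=(0, 1, 2))`) printed:

```
full       auc 0.642  aupr 0.627  accuracy 0.610  f1 0.583
na         auc 0.631  aupr 0.618
nho        auc 0.622  aupr 0.603
scrambled  auc 0.507  aupr 0.514
```

Reading the numbers: the full model recovers a large part of the
planted structure — under these generator settings the Bayes-optimal
AUC is ≈0.81 (matched-block membership is all there is to learn; see
`docs/methods.md`), while the entry-scrambled control, which destroys
the planted blocks at equal density, sits at chance (0.5), confirming
no information leaks from held-out edges into training. Dropping the
homogeneous KNN branch (`nho`) or freezing the metapath weights
uniform (`na`) both cost accuracy, so both attention levels
contribute.

`hganlda rank` prints the top candidates with their sigmoid scores;
the command above prints

```
1       l019    0.755535
2       l091    0.755350
3       l013    0.754689
4       l031    0.746675
5       l097    0.746192
```

after disease `d007`'s known links were held out of training. All five
(l019, l091, l013, l031, l097) belong to the same planted block as
`d007` — the model retrieves the community structure rather than the
memorised edges.

## Command-line interface

`simulate` (synthetic data), `similarity` (write LSS/DSS/GIP/LSM/DSM
matrices), `build` (write metapath and KNN adjacencies), `train`
(full cross-validated pipeline; writes `metrics.tsv`, per-fold scores,
ROC/PR coordinates and a reproducibility manifest), `evaluate` (print
a finished run's metrics), `rank` (case-study candidate ranking). All
input formats are plain text: FASTA, two-column TSV edge lists with
headers, one-id-per-line node universes, YAML configs.
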