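# cetriad

Prediction of associations between **ceRNA triplets** (lncRNA–miRNA–mRNA)
and **diseases** on a heterogeneous biological network, using higher-order
(triangle-motif) graph attention and convolution.

Under the competing-endogenous-RNA hypothesis, lncRNAs and mRNAs regulate
each other by competing for shared miRNA binding sites; a *triplet* is a
trio whose internal lncRNA–miRNA and miRNA–mRNA interactions are
experimentally validated. `cetriad` scores candidate triplet–disease
links, a task relevant to anyone prioritizing ceRNA axes for disease
follow-up when experimental screening of all combinations is infeasible.

## Method

1. **Similarity.** RNA–RNA similarity is the cosine similarity of
   skip-gram embeddings trained on biased (node2vec-style, parameters
   *p*, *q*) random walks over the full heterogeneous association graph;
   noise nodes for negative sampling are drawn with `P_n(v) ∝ d(v)^{3/4}`.
   Disease–disease similarity uses ontology-DAG semantic similarity

       D_d(d) = 1,  D_d(X) = μ · max { D_d(X') : X' child of X },
       DV(d) = Σ_{X ∈ N_d} D_d(X),
       DS(i,j) = Σ_{X ∈ N_i ∩ N_j} (D_i(X) + D_j(X)) / (DV(i) + DV(j))

   with μ = 0.5, falling back to the Gaussian interaction-profile (GIP)
   kernel `GS(i,j) = exp(−Δ_d ‖β(d_i) − β(d_j)‖²)` for diseases without
   ontology annotation, where Δ_d is the reciprocal mean squared profile
   norm.
2. **Higher-order structure.** A support graph joins association edges
   with intra-type similarity edges at threshold τ (default 0.5). Its
   3-cliques define (a) attention sharing — GAT coefficients on the three
   edges of a triangle are replaced by their maximum, iterated to a
   fixpoint — and (b) the binary co-occurrence blocks `H_type` on the
   diagonal of the higher-order adjacency `A_h`.
3. **Propagation and scoring.** With `A_e` the similarity+attention
   enhanced adjacency,

       H = A_h · LeakyReLU(A_e · H⁽⁰⁾ · W⁽¹⁾) · W⁽²⁾,
       ŷ = sigmoid(h_triplet · W_p · h_disease),

   where `h_triplet` is an MLP on the concatenated member embeddings (a
   learned weighted average is also available). Training minimizes binary
   cross-entropy with Adam (300 epochs, lr 0.001, dropout 0.5, hidden 128,
   embedding 64). A LightGBM or logistic head on `[h_triplet | h_disease]`
   can replace the bilinear scorer.
4. **Negative sampling.** Negatives keep the miRNA of a seed positive
   fixed, swap the lncRNA/mRNA among that miRNA's validated partners, and
   draw a disease not linked to the triplet — never overlapping positives,
   with a per-disease quota keeping marginals consistent.

All models are plain NumPy with closed-form gradients, so every run is
exactly reproducible from its seed.

## Worked example

```python
from cetriad import pipeline
from cetriad.synthetic import PRESETS

cfg = pipeline.ExperimentConfig(synth=PRESETS["tiny"], seed=0).reseeded(0)
res = pipeline.run_experiment(cfg)
m = res.metrics
print(f"held-out AUC-ROC {m.auc_roc:.3f}  AUC-PR {m.auc_pr:.3f}  "
      f"ACC {m.accuracy:.3f}  F1 {m.f1:.3f}  (threshold {m.threshold:.3f})")
print(f"triangles in support graph: {len(res.extras['adj']['triangles'])}")
```

prints

```
held-out AUC-ROC 0.782  AUC-PR 0.777  ACC 0.738  F1 0.774  (threshold 0.055)
triangles in support graph: 1761
```

on the 135-node `tiny` benchmark: the model recovers most of the planted
module structure from an 80/20 holdout; the threshold is the
F1-maximizing operating point on the held-out scores. On the larger
`mid` preset (420 nodes, 2000 positives) held-out AUC-ROC reaches ≈0.88,
and a label-permuted control collapses to ≈0.5.

The ontology pieces are available directly:

```python
from cetriad.similarity import DiseaseDAG, semantic_value, semantic_similarity
dag = DiseaseDAG([("A", "B"), ("A", "C")], mu=0.5)
semantic_value(dag, "B")        # 1.5
semantic_similarity(dag, "B", "C")  # 0.3333...
```

## Command line

```bash
cetriad simulate --preset tiny --seed 0 --out bundle/
cetriad train --edges bundle/edges.tsv --dag bundle/dag.tsv \
              --positives bundle/positives.tsv --out run/
cetriad evaluate --scores run/test_scores.tsv --out metrics.json
```

Other subcommands: `similarity`, `build`, `sample-negatives`,
`cv` (random or disease-stratified cold-start folds), `rank`.
All formats are plain TSV/JSON/YAML.

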