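# Methods

This note documents the model, its parameters and defaults, the synthetic
benchmark, and the numerical and design choices behind `cetriad`.

## Model

The data are a four-type heterogeneous network — lncRNA, miRNA, mRNA,
disease — with only inter-type association edges, assembled into the
block adjacency `R` (order lnc, mi, mr, dis; off-diagonal blocks are the
six association matrices, diagonal blocks are per-type similarity). The
prediction unit is a (lncRNA, miRNA, mRNA, disease) quadruple whose
triplet part has validated internal interactions.

**RNA similarity** is network-derived: biased second-order random walks
(return parameter `p`, in-out parameter `q`; transition weight 1/p back
to the previous node, 1 to a common neighbor, 1/q outward) generate a
corpus over the whole association graph; a skip-gram model with negative
sampling (noise ∝ degree^{3/4}) learns embeddings; cosine similarity of
embeddings fills the per-type blocks. Precomputed functional similarity,
if supplied, overrides the network value pairwise (no averaging): the
network similarity exists to complement incomplete functional coverage.
Walks run once on the combined heterogeneous graph rather than per RNA
type — the walk corpus then reflects cross-type context, and per-type
blocks are extracted afterwards.

**Disease similarity** uses Wang-style ontology semantics: contribution
`D_d(X)` decays by μ = 0.5 per generation along the DAG, `DV(d)` sums
contributions over the ancestry, and `DS(i,j)` is the shared-ancestry
ratio. Diseases without ontology annotation fall back to the GIP kernel
over binary interaction profiles, with bandwidth the reciprocal mean
squared profile norm.

**Higher-order structure.** Same-type nodes share no association edges,
so triangles containing same-type pairs cannot exist in the raw
association graph. The *support graph* therefore adds intra-type edges
where similarity ≥ τ (default 0.5, configurable); its 3-cliques are the
triangle set. This is the minimal construction that makes same-type
triangle co-occurrence non-vacuous, and τ is exposed because the choice
of host graph is genuinely open.

**Attention.** One single-head GAT layer over the support graph, computed
once from i.i.d. standard-normal node features with a fixed seed (static
augmentation, not re-estimated during GCN training — the coefficients
enter the enhanced adjacency as additive constants). Row-softmax
coefficients are asymmetric while the similarity blocks they augment are
symmetric, so pairs are symmetrized by the max before sharing; triangle
sharing (each triangle's three edges take their maximum) is iterated to
its fixpoint, i.e. every connected component of edge-sharing triangles
carries the component maximum — a single pass would be order-dependent.

**Propagation and scoring.** Two layers:
`H = A_h · LeakyReLU(A_e · H0 · W1) · W2` (LeakyReLU slope 0.2, dropout
0.5 on the hidden layer during training). Triplets are embedded by a
two-layer MLP on the concatenation (default) or a softmax-weighted
average of the three member embeddings — both paths are implemented
because both constructions are natural here, with the MLP as the
canonical route. Link probability is `sigmoid(h_t · Wp · h_d)`. Training
is full-batch Adam on binary cross-entropy, 1:1 positives:negatives per
epoch (negatives subsampled from the pool each epoch), 300 epochs,
lr 0.001, hidden 128, embedding 64, train ratio 0.8. The adjacencies are
fed unnormalized by default; symmetric normalization
`D^{-1/2}(A+I)D^{-1/2}` is available for numerical stability on denser
graphs. Loss, optimizer and initialization are this package's choices:
they are the standard ones for a sigmoid link score.

Everything is NumPy with hand-derived gradients (verified against central
finite differences in the test suite), which keeps runs bit-reproducible
under a seed on any machine with the same BLAS.

## Negative sampling

A seed positive is drawn uniformly; its miRNA is kept; lncRNA and mRNA
are redrawn uniformly from that miRNA's validated partner lists
(including the originals with natural probability — replacement is
allowed, not forced); the disease is drawn from those not linked to the
triplet. Candidate disease sets are precomputed per triplet. Negatives
never collide with positives or each other; a per-disease quota of
⌈2n / #diseases-in-positives⌉ bounds disease skew; drawing seed positives
uniformly makes the miRNA marginal track the positives by construction.
Fully-associated triplets (every disease already positive) trigger a
re-draw of the seed triplet. The sampler gives up after 100·n attempts
with a diagnostic error rather than looping forever.

## Synthetic benchmarks

The generator plants a modular signal: every node type is partitioned
round-robin into `n_modules` modules; lncRNA–miRNA and miRNA–mRNA edges
appear with probability `p_intra` within a module and `p_noise` across;
the remaining blocks get sparse `p_noise` background edges. A positive
pairs a uniformly drawn valid triplet with a disease from the miRNA's
module with probability `signal`, else a uniform disease. The disease
ontology is a forest with one root per module and random trees beneath,
so semantic similarity clusters by module.

Presets:

| preset   | lnc/mi/mr/dis | modules | p_intra | p_noise | positives | signal |
|----------|---------------|---------|---------|---------|-----------|--------|
| tiny     | 20/40/60/15   | 3       | 0.30    | 0.02    | 200       | 0.9    |
| mid      | 60/120/180/60 | 6       | 0.15    | 0.005   | 2000      | 0.9    |
| dataset1 | 218/605/1051/314 | 20   | 0.05    | 0.002   | 2115      | 0.9    |

`dataset1` mirrors the scale of the curated human ceRNA–disease corpus
the method targets (2115 triplet–disease associations). `mid` is the
routine end-to-end benchmark: large enough that a permuted-label control
has a tight null distribution (400 held-out positives give a chance-AUC
standard error near 0.02), small enough that one 300-epoch training run
takes tens of seconds on a single CPU. `tiny` keeps unit tests fast.

What the generator does *not* emulate: expression measurements and
differential-expression filtering, weighted or directed regulation,
literature biases in which associations get validated, and realistic
degree heavy-tails. Passing tests therefore demonstrate that the
implementation recovers a planted modular signal under the stated
protocol — not that the method attains any particular accuracy on real
curated corpora.

## Evaluation protocol

Held-out evaluation splits positives 80/20; the training graph (and all
similarity computation) uses training positives only, so test edges are
never visible to the model. Test negatives are drawn disjoint from
training negatives. Metrics: rank-formula AUC-ROC (ties one half),
step-integrated AUC-PR, and accuracy/precision/recall/F1 at the
F1-maximizing threshold (the published operating threshold of this model
family, 0.55, is data-dependent and therefore a configurable default,
not a constant). Repeated holdout (30 repeats) reports mean ± sd.
Disease-stratified cross-validation packs diseases into k folds greedy
largest-first by sample count; a hard assertion guarantees no disease
spans folds (cold-start). Welch's t-test (Welch–Satterthwaite df)
compares AUC runs between configurations; fold-similarity diagnostics
compare intra- vs inter-fold disease similarity distributions. Network
topology is profiled by mean eigenvector (power iteration,
L2-normalized), closeness (component-normalized Wasserman–Faust) and
degree centrality.

## Numerical choices and degenerate inputs

- Skip-gram updates are vectorized minibatch SGD with linearly decaying
  learning rate (0.025). The batch size adapts to the vocabulary
  (≈2·|V|, clamped to [512, 8192]) so that summed within-batch updates of
  a node stay close to sequential SGD; individual steps are clipped to
  ±0.5 and scores to ±30. Without this, small dense graphs accumulate
  hundreds of same-node updates computed at stale parameters and diverge.
- Sigmoid arguments are clipped (±500) and probabilities clamped to
  [1e-12, 1−1e-12] inside the cross-entropy.
- Ties in the semantic-contribution max are benign (max semantics); ties
  in ranking are broken lexicographically on ids; ties in AUC count ½.
- Isolated nodes: walks of length 1; no attention row; zero similarity
  handled by the GIP fallback requiring at least one nonzero profile.
- Zero-variance Welch comparisons with equal means return p = 1.
- Symmetric normalization adds self-loops, so zero-degree rows stay
  positive.

## Known limitations

- The GCN is full-batch and dense-ish; beyond ~10⁴ nodes, mini-batching
  and sparse similarity thresholds would be needed.
- Attention is static (single head, fixed random features); joint
  training of the attention parameters with the GCN loss is out of scope.
- The boosted-tree head's hyperparameters (200 trees, depth 6, lr 0.05)
  are conservative defaults, exposed in configuration rather than tuned.
- MISIM-style functional similarity is consumed only as an optional
  precomputed matrix; computing it from annotation corpora is out of
  scope, as are reproduction of external benchmark tables and any
  web-service layer.
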