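"""Node and disease similarity.

RNA similarity is computed from the network itself: biased (node2vec-style)
random walks over the heterogeneous association graph, a skip-gram model
with negative sampling trained on the walk corpus, and cosine similarity of
the learned embeddings.  Disease similarity combines ontology-DAG semantic
similarity (geometric decay ``mu`` per generation, shared-ancestor ratio)
with the Gaussian interaction profile (GIP) kernel as a fallback for
diseases without ontology annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from ._util import check_symmetric

__all__ = [
    "WalkConfig",
    "EmbeddingTable",
    "DiseaseDAG",
    "SimilarityMatrix",
    "biased_transition_probs",
    "generate_walks",
    "train_node_embeddings",
    "cosine_similarity_matrix",
    "semantic_contribution",
    "semantic_value",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity",
    "assemble_disease_similarity",
    "assemble_rna_similarity",
]


@dataclass(frozen=True)
class WalkConfig:
    """Biased random-walk parameters.

    ``p`` is the return parameter (probability weight 1/p of stepping back
    to the previous node), ``q`` the in-out parameter (weight 1/q of moving
    to a node not adjacent to the previous one).  p = q = 1 gives unbiased
    first-order walks.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be > 0")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")


@dataclass
class EmbeddingTable:
    """Dense node embeddings: ``ids[i]`` labels row i of ``vectors``."""

    ids: list
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids / vectors length mismatch")
        self._pos = {n: i for i, n in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node) -> bool:
        return node in self._pos

    def __getitem__(self, node) -> np.ndarray:
        return self.vectors[self._pos[node]]


class DiseaseDAG:
    """Directed acyclic parent->child structure over disease terms.

    ``mu`` in (0, 1] is the semantic contribution factor: each generation
    up the ancestry multiplies the contribution by ``mu``.
    """

    def __init__(self, edges, nodes=None, mu: float = 0.5):
        if not (0 < mu <= 1):
            raise ValueError("mu must be in (0, 1]")
        self.mu = float(mu)
        self.graph = nx.DiGraph()
        if nodes is not None:
            self.graph.add_nodes_from(nodes)
        self.graph.add_edges_from(edges)  # (parent, child)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("disease DAG contains a cycle")
        self._ancestor_cache: dict = {}

    @property
    def nodes(self):
        return set(self.graph.nodes)

    def __contains__(self, d) -> bool:
        return d in self.graph

    def children(self, X):
        return list(self.graph.successors(X))

    def ancestry(self, d) -> set:
        """N_d: the disease itself plus all its ancestors."""
        if d not in self.graph:
            raise KeyError(f"unknown disease {d!r}")
        if d not in self._ancestor_cache:
            self._ancestor_cache[d] = nx.ancestors(self.graph, d) | {d}
        return self._ancestor_cache[d]


@dataclass
class SimilarityMatrix:
    """Square symmetric per-type similarity with an explicit node order."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        check_symmetric(self.values, what="similarity matrix")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids / matrix size mismatch")
        self._pos = {n: i for i, n in enumerate(self.ids)}

    def loc(self, i, j) -> float:
        return float(self.values[self._pos[i], self._pos[j]])


# ---------------------------------------------------------------------------
# biased random walks + skip-gram


def biased_transition_probs(graph: nx.Graph, prev, curr, cfg: WalkConfig) -> dict:
    """Second-order transition distribution over the neighbors of ``curr``.

    Candidate weights: 1/p if the candidate is ``prev`` itself, 1 if it is
    adjacent to ``prev`` (distance 1), 1/q otherwise (distance 2).  With no
    previous node (walk start) the distribution is uniform.
    """
    nbrs = list(graph.neighbors(curr))
    if not nbrs:
        raise ValueError(f"node {curr!r} is isolated: no transition possible")
    if prev is None:
        w = np.ones(len(nbrs))
    else:
        if not graph.has_edge(prev, curr):
            raise ValueError("prev must be a neighbor of curr")
        prev_adj = set(graph.neighbors(prev))
        w = np.array(
            [
                1.0 / cfg.p if c == prev else (1.0 if c in prev_adj else 1.0 / cfg.q)
                for c in nbrs
            ]
        )
    w /= w.sum()
    return dict(zip(nbrs, w))


def generate_walks(graph: nx.Graph, cfg: WalkConfig) -> list:
    """Simulate ``walks_per_node`` biased walks from every node.

    Isolated nodes yield length-1 walks.  Fully reproducible under
    ``cfg.seed``; node iteration order is sorted for stability.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(cfg.seed)
    adj = {n: sorted(graph.neighbors(n)) for n in graph.nodes}
    adj_sets = {n: set(v) for n, v in adj.items()}
    inv_p, inv_q = 1.0 / cfg.p, 1.0 / cfg.q
    walks = []
    nodes = sorted(graph.nodes)
    for _ in range(cfg.walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < cfg.walk_length:
                curr = walk[-1]
                nbrs = adj[curr]
                if not nbrs:
                    break
                if len(walk) == 1:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    prev = walk[-2]
                    prev_adj = adj_sets[prev]
                    w = np.fromiter(
                        (
                            inv_p if c == prev else (1.0 if c in prev_adj else inv_q)
                            for c in nbrs
                        ),
                        dtype=float,
                        count=len(nbrs),
                    )
                    w /= w.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return walks


def train_node_embeddings(
    walks: list,
    dim: int = 64,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 3,
    seed: int = 0,
    degrees: dict | None = None,
    lr: float = 0.025,
) -> EmbeddingTable:
    """Skip-gram with negative sampling on a random-walk corpus.

    Maximizes log sigma(z_u . z_v) for observed (center, context) pairs
    within ``window`` plus ``negatives`` noise terms log sigma(-z_n . z_v)
    with noise distribution P_n(v) proportional to degree(v)**(3/4).  If
    ``degrees`` is not supplied, degrees are estimated as the number of
    distinct walk neighbors of each node.  Deterministic under ``seed``.
    """
    if dim <= 0:
        raise ValueError("embedding dimension must be positive")
    if not walks:
        raise ValueError("empty walk corpus")

    vocab = sorted({n for w in walks for n in w})
    pos = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)

    if degrees is None:
        nbr: dict = {n: set() for n in vocab}
        for w in walks:
            for a, b in zip(w, w[1:]):
                if a != b:
                    nbr[a].add(b)
                    nbr[b].add(a)
        deg = np.array([max(len(nbr[n]), 1) for n in vocab], dtype=float)
    else:
        deg = np.array([max(float(degrees.get(n, 0.0)), 1e-12) for n in vocab])
    noise = deg**0.75
    noise /= noise.sum()

    # (center, context) pairs from all windows
    centers, contexts = [], []
    for w in walks:
        idx = [pos[n] for n in w]
        L = len(idx)
        for i, c in enumerate(idx):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(idx[j])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus yields no training pairs")

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    # keep within-batch repeats of any node small: summed minibatch updates
    # approximate sequential SGD only while batch/vocabulary stays modest
    batch = int(min(8192, max(512, 2 * V)))
    total_steps = max(epochs * n_pairs, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            b = order[s : s + batch]
            cv, cu = centers[b], contexts[b]
            neg = rng.choice(V, size=(len(b), negatives), p=noise)
            cur_lr = lr * max(1.0 - step / total_steps, 1e-4)
            step += len(b)

            zv = w_in[cv]  # (B, d)
            zu = w_out[cu]  # (B, d)
            zn = w_out[neg]  # (B, K, d)

            s_pos = np.clip(np.einsum("bd,bd->b", zv, zu), -30, 30)
            s_neg = np.clip(np.einsum("bkd,bd->bk", zn, zv), -30, 30)
            g_pos = 1.0 / (1.0 + np.exp(s_pos)) * cur_lr
            # sigma(-x) for negatives: gradient pushes scores down
            g_neg = 1.0 / (1.0 + np.exp(-s_neg)) * cur_lr

            d_zv = g_pos[:, None] * zu - np.einsum("bk,bkd->bd", g_neg, zn)
            d_zu = g_pos[:, None] * zv
            d_zn = -g_neg[..., None] * zv[:, None, :]

            np.add.at(w_in, cv, np.clip(d_zv, -0.5, 0.5))
            np.add.at(w_out, cu, np.clip(d_zu, -0.5, 0.5))
            np.add.at(w_out, neg.ravel(), np.clip(d_zn.reshape(-1, dim), -0.5, 0.5))

    return EmbeddingTable(vocab, w_in)


def sgns_objective(emb_in: np.ndarray, emb_out: np.ndarray, centers, contexts, neg, eps=1e-12) -> float:
    """Mean skip-gram negative-sampling log-likelihood of a pair sample.

    Used to monitor training; higher is better.
    """
    zv, zu, zn = emb_in[centers], emb_out[contexts], emb_out[neg]
    pos = np.log(1.0 / (1.0 + np.exp(-np.einsum("bd,bd->b", zv, zu))) + eps)
    negt = np.log(1.0 / (1.0 + np.exp(np.einsum("bkd,bd->bk", zn, zv))) + eps).sum(axis=1)
    return float(np.mean(pos + negt))


def cosine_similarity_matrix(emb: EmbeddingTable, nodes=None) -> SimilarityMatrix:
    """Pairwise cosine similarity of node embeddings."""
    nodes = list(emb.ids) if nodes is None else list(nodes)
    missing = [n for n in nodes if n not in emb]
    if missing:
        raise KeyError(f"nodes without embeddings: {missing[:5]}")
    Z = np.stack([emb[n] for n in nodes])
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise FloatingPointError("zero-norm embedding vector")
    Zn = Z / norms[:, None]
    S = np.clip(Zn @ Zn.T, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(nodes, S)


# ---------------------------------------------------------------------------
# disease semantic similarity


def semantic_contribution(dag: DiseaseDAG, d, X) -> float:
    """Contribution D_d(X) of ancestor X to disease d.

    D_d(d) = 1; for a proper ancestor, mu times the best contribution among
    its children that lie on a path to d.
    """
    anc = dag.ancestry(d)
    if X not in anc:
        raise KeyError(f"{X!r} is not {d!r} or an ancestor of it")
    memo: dict = {d: 1.0}

    def rec(node) -> float:
        if node in memo:
            return memo[node]
        vals = [rec(c) for c in dag.children(node) if c in anc]
        memo[node] = dag.mu * max(vals)
        return memo[node]

    return rec(X)


def semantic_value(dag: DiseaseDAG, d) -> float:
    """DV(d): sum of contributions over the whole ancestry of d."""
    return sum(semantic_contribution(dag, d, X) for X in dag.ancestry(d))


def semantic_similarity(dag: DiseaseDAG, i, j) -> float:
    """Shared-ancestry semantic similarity DS(i, j) in [0, 1]."""
    if i == j:
        return 1.0
    shared = dag.ancestry(i) & dag.ancestry(j)
    if not shared:
        return 0.0
    num = sum(
        semantic_contribution(dag, i, X) + semantic_contribution(dag, j, X)
        for X in shared
    )
    return num / (semantic_value(dag, i) + semantic_value(dag, j))


def semantic_similarity_matrix(dag: DiseaseDAG, diseases) -> SimilarityMatrix:
    diseases = list(diseases)
    n = len(diseases)
    S = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            S[a, b] = S[b, a] = semantic_similarity(dag, diseases[a], diseases[b])
    return SimilarityMatrix(diseases, S)


# ---------------------------------------------------------------------------
# GIP kernel


def gip_bandwidth(assoc_rows: np.ndarray) -> float:
    """Kernel bandwidth: reciprocal of the mean squared profile norm."""
    rows = np.asarray(assoc_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1:
        raise ValueError("need at least one interaction profile")
    mean_sq = float(np.mean(np.sum(rows**2, axis=1)))
    if mean_sq == 0:
        raise ZeroDivisionError("all interaction profiles are zero")
    return 1.0 / mean_sq


def gip_similarity(assoc_matrix: np.ndarray, ids=None) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profiles."""
    A = np.asarray(assoc_matrix, dtype=float)
    if A.size == 0:
        raise ValueError("empty association matrix")
    delta = gip_bandwidth(A)
    d2 = squareform(pdist(A, metric="sqeuclidean")) if A.shape[0] > 1 else np.zeros((1, 1))
    S = np.exp(-delta * d2)
    np.fill_diagonal(S, 1.0)
    if ids is None:
        ids = list(range(A.shape[0]))
    return SimilarityMatrix(list(ids), S)


# ---------------------------------------------------------------------------
# assembly


def assemble_disease_similarity(
    dag: DiseaseDAG | None, assoc_matrix: np.ndarray, disease_ids
) -> SimilarityMatrix:
    """Fuse semantic and GIP similarity into the disease block A_D.

    Pairs where both diseases carry ontology annotation use semantic
    similarity; every other pair falls back to the GIP kernel.
    """
    disease_ids = list(disease_ids)
    gip = gip_similarity(assoc_matrix, disease_ids)
    if dag is None:
        return gip
    A = np.asarray(assoc_matrix)
    has_profile = np.asarray(A).sum(axis=1) > 0
    for k, d in enumerate(disease_ids):
        if d not in dag and not has_profile[k]:
            raise ValueError(f"disease {d!r} has neither DAG membership nor profile")
    in_dag = np.array([d in dag for d in disease_ids])
    S = gip.values.copy()
    dag_idx = np.where(in_dag)[0]
    for a in dag_idx:
        for b in dag_idx:
            if b > a:
                S[a, b] = S[b, a] = semantic_similarity(
                    dag, disease_ids[a], disease_ids[b]
                )
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(disease_ids, S)


def assemble_rna_similarity(
    network_sim: SimilarityMatrix,
    functional_sim: SimilarityMatrix | None = None,
    functional_mask: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Per-type RNA similarity block.

    Functional similarity, where provided, overrides the network-embedding
    similarity; uncovered pairs keep the network value.  ``functional_mask``
    marks the covered entries (default: everywhere, if ``functional_sim``
    is given).
    """
    if functional_sim is None:
        return network_sim
    if list(functional_sim.ids) != list(network_sim.ids):
        raise ValueError("functional similarity index does not match network index")
    S = network_sim.values.copy()
    F = functional_sim.values
    if functional_mask is None:
        mask = np.ones_like(S, dtype=bool)
    else:
        mask = np.asarray(functional_mask, dtype=bool)
        if mask.shape != S.shape:
            raise ValueError("functional mask shape mismatch")
        mask = mask | mask.T  # keep the block symmetric
    S[mask] = F[mask]
    return SimilarityMatrix(list(network_sim.ids), (S + S.T) / 2.0)
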