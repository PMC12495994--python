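"""Higher-order graph attention.

Pairwise attention coefficients are computed with a single-head GAT layer
over the support graph (softmax over each node's neighborhood), then made
symmetric and shared across triangle motifs: the three edges of any
triangle all carry the maximum of their individual coefficients.  The
resulting map additively augments the per-type similarity blocks that sit
on the diagonal of the enhanced adjacency A_e.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .hetnet import TriangleSet
from .similarity import SimilarityMatrix


@dataclass
class AttentionParams:
    """Single-head attention parameters.

    ``W0`` projects node features to the attention space; ``W`` scores the
    concatenation of two projected features; ``leaky_slope`` is the
    LeakyReLU negative slope.
    """

    W: np.ndarray  # (2 * d_att,)
    W0: np.ndarray  # (d_feat, d_att)
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float).ravel()
        self.W0 = np.asarray(self.W0, dtype=float)
        if self.W.shape[0] != 2 * self.W0.shape[1]:
            raise ValueError("W must have length 2 * W0.shape[1]")


def random_attention_inputs(
    nodes, d_feat: int = 16, d_att: int = 8, seed: int = 0, leaky_slope: float = 0.2
):
    """Random node features plus attention parameters (the model's inputs).

    Node features are i.i.d. standard normal; parameters are scaled
    normals.  Everything is determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    nodes = list(nodes)
    feats = {n: rng.standard_normal(d_feat) for n in nodes}
    params = AttentionParams(
        W=rng.standard_normal(2 * d_att) / np.sqrt(2 * d_att),
        W0=rng.standard_normal((d_feat, d_att)) / np.sqrt(d_feat),
        leaky_slope=leaky_slope,
    )
    return feats, params


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def attention_coefficients(
    features: dict, support_graph: nx.Graph, params: AttentionParams
) -> dict:
    """Directed attention map {(i, j): alpha'_ij} over support-graph edges.

    alpha'_ij = softmax_{b in N(i)} LeakyReLU(W . [W0 h_i || W0 h_j]);
    each node's row sums to 1 over its neighborhood.  Nodes without
    neighbors simply contribute no entries.

    The score decomposes as s_ij = a_src(i) + a_dst(j) with
    a_src = (W0 h) . W[:d] and a_dst = (W0 h) . W[d:], which lets the
    softmax be computed per-row without materializing pair features.
    """
    d_att = params.W0.shape[1]
    nodes = list(support_graph.nodes)
    missing = [n for n in nodes if n not in features]
    if missing:
        raise KeyError(f"nodes without features: {missing[:5]}")
    proj = {n: np.asarray(features[n], dtype=float) @ params.W0 for n in nodes}
    a_src = {n: float(proj[n] @ params.W[:d_att]) for n in nodes}
    a_dst = {n: float(proj[n] @ params.W[d_att:]) for n in nodes}

    attn: dict = {}
    for i in nodes:
        nbrs = sorted(support_graph.neighbors(i))
        if not nbrs:
            continue
        scores = _leaky_relu(
            np.array([a_src[i] + a_dst[j] for j in nbrs]), params.leaky_slope
        )
        scores -= scores.max()  # stable softmax
        e = np.exp(scores)
        e /= e.sum()
        for j, a in zip(nbrs, e):
            attn[(i, j)] = float(a)
    return attn


def symmetrize_attention(attn: dict) -> dict:
    """Undirected map: alpha_ij = max(alpha'_ij, alpha'_ji).

    Row-softmax coefficients are asymmetric; the diagonal similarity
    blocks they augment are symmetric, so the larger direction wins
    (consistent with the max semantics of triangle sharing).
    """
    out: dict = {}
    for (i, j), a in attn.items():
        k = (i, j) if i <= j else (j, i)
        out[k] = max(out.get(k, 0.0), a)
    return out


def share_triangle_attention(attn: dict, triangles: TriangleSet) -> dict:
    """Propagate the maximum coefficient across each triangle's edges.

    Triangles that share an edge interact, so the max is iterated to its
    fixpoint: every connected component of edge-sharing triangles ends up
    carrying the component-wide maximum.  Implemented with union-find over
    triangle edges; non-triangle edges are untouched.  Keys of ``attn``
    must be sorted undirected pairs (see :func:`symmetrize_attention`).
    """
    parent: dict = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    tri_edges = set()
    for tri in triangles:
        a, b, c = tri
        edges = [tuple(sorted(p)) for p in ((a, b), (a, c), (b, c))]
        for e in edges:
            if e not in attn:
                raise KeyError(f"triangle edge {e} missing from attention map")
            if e not in parent:
                parent[e] = e
            tri_edges.add(e)
        union(edges[0], edges[1])
        union(edges[0], edges[2])

    comp_max: dict = {}
    for e in tri_edges:
        r = find(e)
        comp_max[r] = max(comp_max.get(r, 0.0), attn[e])

    out = dict(attn)
    for e in tri_edges:
        out[e] = comp_max[find(e)]
    return out


def augment_similarity(block: SimilarityMatrix, attn: dict) -> SimilarityMatrix:
    """Additively fuse attention into a same-type similarity block.

    A~(i, j) = A(i, j) + alpha_ij where an (undirected) coefficient
    exists for the pair, A(i, j) otherwise; the diagonal is untouched.
    """
    ids = list(block.ids)
    pos = {n: k for k, n in enumerate(ids)}
    S = block.values.copy()
    for (i, j), a in attn.items():
        ki, kj = pos.get(i), pos.get(j)
        if ki is None or kj is None or ki == kj:
            continue
        S[ki, kj] += a
        S[kj, ki] += a
    return SimilarityMatrix(ids, S)
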