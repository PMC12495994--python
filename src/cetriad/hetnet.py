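"""Heterogeneous network assembly.

The network has four node types — lncRNA, miRNA, mRNA, disease — and only
inter-type association edges.  The block adjacency R places the six
association blocks off the diagonal; the diagonal blocks are reserved for
per-type similarity (enhanced adjacency A_e) or for the binary triangle
co-occurrence blocks H (higher-order adjacency A_h).  Triangles live on a
"support graph": association edges plus intra-type edges wherever the
similarity of a same-type pair clears a threshold tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

TYPE_ORDER = ("lnc", "mi", "mr", "dis")
RELATIONS = ("lnc-mi", "lnc-mr", "lnc-dis", "mi-mr", "mi-dis", "mr-dis")

_REL_TYPES = {r: tuple(r.split("-")) for r in RELATIONS}


@dataclass
class HeteroGraph:
    """Typed node sets plus inter-type association edge lists.

    ``nodes`` maps each type in TYPE_ORDER to an ordered list of node ids;
    ``edges`` maps each relation tag to a set of (source_id, target_id)
    pairs where the source type is the first half of the tag.
    """

    nodes: dict = field(default_factory=lambda: {t: [] for t in TYPE_ORDER})
    edges: dict = field(default_factory=lambda: {r: set() for r in RELATIONS})

    def __post_init__(self) -> None:
        for t in TYPE_ORDER:
            self.nodes.setdefault(t, [])
        for r in RELATIONS:
            self.edges.setdefault(r, set())
        self.validate()

    def validate(self) -> None:
        seen: dict = {}
        for t in TYPE_ORDER:
            for n in self.nodes[t]:
                if n in seen:
                    raise ValueError(f"node id {n!r} appears in types {seen[n]} and {t}")
                seen[n] = t
        for rel, pairs in self.edges.items():
            st, tt = _REL_TYPES[rel]
            for a, b in pairs:
                if seen.get(a) != st or seen.get(b) != tt:
                    raise ValueError(f"edge ({a!r}, {b!r}) inconsistent with relation {rel}")

    # -- structure ---------------------------------------------------------
    def node_type(self, n) -> str:
        for t in TYPE_ORDER:
            if n in self._type_sets[t]:
                return t
        raise KeyError(n)

    @property
    def _type_sets(self) -> dict:
        return {t: set(self.nodes[t]) for t in TYPE_ORDER}

    def all_nodes(self) -> list:
        return [n for t in TYPE_ORDER for n in self.nodes[t]]

    def node_index(self) -> dict:
        """Global id -> integer index in block order lnc, mi, mr, dis."""
        return {n: i for i, n in enumerate(self.all_nodes())}

    def type_slices(self) -> dict:
        out, start = {}, 0
        for t in TYPE_ORDER:
            out[t] = slice(start, start + len(self.nodes[t]))
            start += len(self.nodes[t])
        return out

    @property
    def n_nodes(self) -> int:
        return sum(len(self.nodes[t]) for t in TYPE_ORDER)

    def ensure_nodes(self, node_type: str, ids) -> None:
        """Add any missing ids to a type's node list (kept sorted)."""
        if node_type not in TYPE_ORDER:
            raise ValueError(f"unknown node type {node_type!r}")
        known = set(self.nodes[node_type])
        new = [n for n in ids if n not in known]
        if new:
            self.nodes[node_type] = sorted(known | set(new))
            self.validate()

    def add_edge(self, relation: str, a, b, warn_duplicate: bool = True) -> bool:
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        if (a, b) in self.edges[relation]:
            if warn_duplicate:
                warnings.warn(f"duplicate edge ({a}, {b}) [{relation}] ignored")
            return False
        self.edges[relation].add((a, b))
        return True

    def association_graph(self) -> nx.Graph:
        """Undirected graph of the association edges only (node ids)."""
        g = nx.Graph()
        g.add_nodes_from(self.all_nodes())
        for pairs in self.edges.values():
            g.add_edges_from(pairs)
        return g


@dataclass
class BlockMatrix:
    """A square matrix with recorded per-type block boundaries."""

    matrix: sp.spmatrix
    slices: dict

    def block(self, row_type: str, col_type: str) -> np.ndarray:
        return np.asarray(
            self.matrix[self.slices[row_type], self.slices[col_type]].todense()
        )

    def toarray(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


@dataclass
class TriangleSet:
    """Set of 3-cliques (sorted node-id triples) of a support graph."""

    triangles: set
    support_graph: nx.Graph

    def __len__(self) -> int:
        return len(self.triangles)

    def __iter__(self):
        return iter(self.triangles)


def build_association_matrix(graph: HeteroGraph) -> BlockMatrix:
    """Binary block adjacency R with zero (placeholder) diagonal blocks."""
    idx = graph.node_index()
    rows, cols = [], []
    for rel, pairs in graph.edges.items():
        for a, b in pairs:
            if a not in idx or b not in idx:
                raise KeyError(f"edge references unknown node: ({a!r}, {b!r})")
            i, j = idx[a], idx[b]
            rows += [i, j]
            cols += [j, i]
    n = graph.n_nodes
    data = np.ones(len(rows))
    R = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    R.data[:] = 1.0  # collapse any accidental duplicates
    return BlockMatrix(R, graph.type_slices())


def build_support_graph(graph: HeteroGraph, sims: dict, tau: float) -> nx.Graph:
    """Association edges plus intra-type similarity edges at >= tau.

    ``sims`` maps a node type to its SimilarityMatrix (index order must
    match ``graph.nodes[type]``); types absent from ``sims`` contribute no
    intra-type edges.  ``tau`` above the similarity range reduces the
    support graph to the association edges alone.
    """
    g = graph.association_graph()
    for t, sim in sims.items():
        if sim is None:
            continue
        ids = list(sim.ids)
        if ids != list(graph.nodes[t]):
            raise ValueError(f"similarity index for type {t!r} does not match graph")
        S = sim.values
        ii, jj = np.where(np.triu(S, k=1) >= tau)
        g.add_edges_from((ids[a], ids[b]) for a, b in zip(ii, jj))
    return g


def enumerate_triangles(support_graph: nx.Graph) -> TriangleSet:
    """All 3-cliques, found by neighbor-set intersection per edge."""
    adj = {n: set(support_graph.neighbors(n)) for n in support_graph.nodes}
    out = set()
    for u, v in support_graph.edges:
        for w in adj[u] & adj[v]:
            out.add(tuple(sorted((u, v, w))))
    return TriangleSet(out, support_graph)


def higher_order_blocks(triangles: TriangleSet, graph: HeteroGraph) -> dict:
    """Binary same-type co-occurrence blocks H_type from the triangle set.

    H_type(i, j) = 1 iff i and j are of that type and some triangle
    contains both; diagonal zero.
    """
    type_of = {}
    pos = {}
    for t in TYPE_ORDER:
        for k, n in enumerate(graph.nodes[t]):
            type_of[n] = t
            pos[n] = k
    pairs: dict = {t: set() for t in TYPE_ORDER}
    for tri in triangles:
        a, b, c = tri
        for x, y in ((a, b), (a, c), (b, c)):
            tx = type_of.get(x)
            if tx is not None and tx == type_of.get(y):
                pairs[tx].add((pos[x], pos[y]))
    blocks = {}
    for t in TYPE_ORDER:
        m = len(graph.nodes[t])
        H = sp.lil_matrix((m, m))
        for i, j in pairs[t]:
            H[i, j] = 1.0
            H[j, i] = 1.0
        blocks[t] = H.tocsr()
    return blocks


def _replace_diagonal_blocks(R: BlockMatrix, diag: dict) -> BlockMatrix:
    A = R.matrix.tolil(copy=True)
    for t, block in diag.items():
        sl = R.slices[t]
        blk = block if sp.issparse(block) else sp.csr_matrix(np.asarray(block, dtype=float))
        if blk.shape != (sl.stop - sl.start, sl.stop - sl.start):
            raise ValueError(f"diagonal block for {t!r} has shape {blk.shape}")
        A[sl, sl] = blk
    return BlockMatrix(A.tocsr(), dict(R.slices))


def build_enhanced_adjacency(R: BlockMatrix, augmented_sims: dict) -> BlockMatrix:
    """A_e: R with diagonal blocks set to attention-augmented similarity."""
    return _replace_diagonal_blocks(R, augmented_sims)


def build_higher_order_adjacency(R: BlockMatrix, h_blocks: dict) -> BlockMatrix:
    """A_h: R with diagonal blocks set to binary triangle co-occurrence."""
    return _replace_diagonal_blocks(R, h_blocks)


def normalize_adjacency(A, mode: str = "none"):
    """Optional symmetric normalization D^{-1/2}(A+I)D^{-1/2}.

    mode="none" returns A untouched (the propagation rule uses raw
    adjacencies by default); self-loops keep every degree positive.
    """
    if mode == "none":
        return A
    if mode != "sym":
        raise ValueError(f"unknown normalization mode {mode!r}")
    M = A.matrix if isinstance(A, BlockMatrix) else A
    dense = not sp.issparse(M)
    M = sp.csr_matrix(M) if dense else M.tocsr()
    n = M.shape[0]
    M = M + sp.eye(n, format="csr")
    d = np.asarray(np.abs(M).sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(d)
    D = sp.diags(dinv)
    out = D @ M @ D
    if isinstance(A, BlockMatrix):
        return BlockMatrix(out.tocsr(), dict(A.slices))
    return np.asarray(out.todense()) if dense else out.tocsr()
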