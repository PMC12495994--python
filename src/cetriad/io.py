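"""Readers and writers for the on-disk formats.

Everything is plain text: 3-column TSV edge lists for the heterogeneous
graph, 2-column parent/child TSV for the disease ontology, 5-column TSV
for labeled samples, labeled dense-matrix TSV for similarities and
embeddings, JSON manifests and YAML configs.  Writers sort rows so output
is byte-stable; readers reject malformed input with the offending line
number rather than coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .hetnet import RELATIONS, HeteroGraph, TYPE_ORDER
from .sampling import TripletSample
from .similarity import DiseaseDAG, EmbeddingTable, SimilarityMatrix

__all__ = [
    "read_graph", "write_graph", "read_samples", "write_samples",
    "read_dag", "write_dag", "read_matrix", "write_matrix",
    "read_config", "write_manifest",
]

_REL_TYPES = {r: tuple(r.split("-")) for r in RELATIONS}


class ParseError(ValueError):
    pass


def _rows(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line.split("\t")


def read_graph(path) -> HeteroGraph:
    """Read a 3-column (source, target, relation) TSV edge list.

    Node types are inferred from the relation tag; a header row (third
    column not a known relation, first line only) is skipped.  Duplicate
    edges are deduplicated.
    """
    nodes: dict = {t: [] for t in TYPE_ORDER}
    seen: dict = {}
    edges: dict = {r: set() for r in RELATIONS}
    n_dup = 0
    for lineno, parts in _rows(path):
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        a, b, rel = (p.strip() for p in parts)
        if rel not in RELATIONS:
            if lineno == 1:  # tolerated header
                continue
            raise ParseError(f"{path}:{lineno}: unknown relation {rel!r}")
        st, tt = _REL_TYPES[rel]
        for n, t in ((a, st), (b, tt)):
            if n in seen:
                if seen[n] != t:
                    raise ParseError(f"{path}:{lineno}: node {n!r} used as both "
                                     f"{seen[n]} and {t}")
            else:
                seen[n] = t
                nodes[t].append(n)
        if (a, b) in edges[rel]:
            n_dup += 1
        edges[rel].add((a, b))
    for t in nodes:
        nodes[t] = sorted(nodes[t])
    return HeteroGraph(nodes=nodes, edges=edges)


def write_graph(graph: HeteroGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\trelation\n")
        for rel in RELATIONS:
            for a, b in sorted(graph.edges[rel]):
                fh.write(f"{a}\t{b}\t{rel}\n")


def read_samples(path) -> list:
    """Read 5-column (lnc, mi, mr, disease, label) TSV samples."""
    out = []
    for lineno, parts in _rows(path):
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        parts = [p.strip() for p in parts]
        if lineno == 1 and parts[4] not in ("0", "1"):
            continue  # header
        if parts[4] not in ("0", "1"):
            raise ParseError(f"{path}:{lineno}: label must be 0 or 1, got {parts[4]!r}")
        out.append(TripletSample(*parts[:4], int(parts[4])))
    return out


def write_samples(samples, path) -> None:
    with open(path, "w") as fh:
        fh.write("lnc\tmi\tmr\tdisease\tlabel\n")
        for s in sorted(samples):
            fh.write(f"{s.lnc}\t{s.mi}\t{s.mr}\t{s.dis}\t{s.label}\n")


def read_dag(path, mu: float = 0.5) -> DiseaseDAG:
    """Read a 2-column (parent, child) TSV; header optional."""
    edges = []
    for lineno, parts in _rows(path):
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        a, b = (p.strip() for p in parts)
        if lineno == 1 and (a.lower(), b.lower()) == ("parent", "child"):
            continue
        edges.append((a, b))
    return DiseaseDAG(edges, mu=mu)


def write_dag(dag: DiseaseDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for a, b in sorted(dag.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_matrix(path):
    """Labeled dense-matrix TSV -> (ids, ndarray)."""
    ids, rows = None, []
    row_ids = []
    for lineno, parts in _rows(path):
        if ids is None:
            ids = [p.strip() for p in parts[1:]]
            continue
        if len(parts) != len(ids) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(ids)+1} columns")
        row_ids.append(parts[0].strip())
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: {e}") from None
    if ids is None:
        raise ParseError(f"{path}: empty matrix file")
    return row_ids, ids, np.array(rows)


def write_matrix(row_ids, col_ids, values, path) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, col_ids)) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(str(rid) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_similarity(sim: SimilarityMatrix, path) -> None:
    write_matrix(sim.ids, sim.ids, sim.values, path)


def read_similarity(path) -> SimilarityMatrix:
    row_ids, col_ids, values = read_matrix(path)
    if row_ids != col_ids:
        raise ParseError(f"{path}: similarity matrix index is not square-consistent")
    return SimilarityMatrix(row_ids, values)


def write_embeddings(emb: EmbeddingTable, path) -> None:
    write_matrix(emb.ids, [f"d{i}" for i in range(emb.dim)], emb.vectors, path)


def read_embeddings(path) -> EmbeddingTable:
    row_ids, _, values = read_matrix(path)
    return EmbeddingTable(row_ids, values)


_KNOWN_CONFIG_KEYS = {
    "preset", "synth", "walk", "train", "embed_dim", "window", "sg_negatives",
    "sg_epochs", "tau", "normalize", "use_attention", "use_higher_order",
    "neg_strategy", "head", "seed",
}


def read_config(path) -> dict:
    """Load a YAML (or JSON) run config; unknown top-level keys rejected."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError:
        cfg = json.loads(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_manifest(path, **fields) -> None:
    """JSON manifest beside an output (resolved config, seeds, shapes)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
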