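"""End-to-end experiment orchestration.

Wires the stages together: synthetic (or loaded) data -> network-embedding
and disease similarity -> support graph, triangles and attention ->
enhanced / higher-order adjacencies -> GCN training -> scoring with the
bilinear link probability and, optionally, a boosted-tree or logistic
head on the learned embeddings.  The association blocks fed to the model
are built from *training* positives only, so held-out evaluation measures
generalization rather than edge recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import classify, hetnet, hogat, hogcn, sampling, similarity
from ._util import derive_seed
from .synthetic import PRESETS, BenchmarkBundle, SynthConfig, generate_benchmark

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "repeated_holdout", "cross_validate"]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; defaults follow the study settings."""

    synth: SynthConfig = field(default_factory=lambda: PRESETS["mid"])
    walk: similarity.WalkConfig = field(default_factory=similarity.WalkConfig)
    embed_dim: int = 64
    window: int = 5
    sg_negatives: int = 5
    sg_epochs: int = 3
    tau: float = 0.5
    normalize: str = "none"
    use_attention: bool = True
    use_higher_order: bool = True
    neg_strategy: str = "high_order"  # or "random"
    train: hogcn.TrainConfig = field(default_factory=hogcn.TrainConfig)
    head: str = "gcn"  # final scorer: "gcn", "gbt" or "logistic"
    seed: int = 0

    def reseeded(self, seed: int) -> "ExperimentConfig":
        return replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=derive_seed(seed, "synth")),
            walk=replace(self.walk, seed=derive_seed(seed, "walks")),
            train=replace(self.train, seed=derive_seed(seed, "gcn")),
        )


@dataclass
class ExperimentResult:
    metrics: classify.MetricsReport
    model: hogcn.TrainedModel
    bundle: BenchmarkBundle
    sims: dict
    test_samples: list
    test_labels: np.ndarray
    test_scores: np.ndarray
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages


def training_graph(bundle: BenchmarkBundle, train_positives) -> hetnet.HeteroGraph:
    """Copy of the bundle graph with RNA-disease edges from train positives."""
    g = hetnet.HeteroGraph(
        nodes={t: list(v) for t, v in bundle.graph.nodes.items()},
        edges={r: set(v) for r, v in bundle.graph.edges.items()},
    )
    for p in train_positives:
        g.edges["lnc-dis"].add((p.lnc, p.dis))
        g.edges["mi-dis"].add((p.mi, p.dis))
        g.edges["mr-dis"].add((p.mr, p.dis))
    return g


def compute_similarities(
    graph: hetnet.HeteroGraph,
    dag: similarity.DiseaseDAG | None,
    cfg: ExperimentConfig,
) -> dict:
    """Per-type similarity blocks.

    RNA types: cosine similarity of skip-gram embeddings trained on biased
    walks over the full heterogeneous association graph.  Diseases:
    ontology semantic similarity where available, GIP kernel elsewhere
    (profiles are the rows of the RNA-disease association block).
    """
    assoc = graph.association_graph()
    walks = similarity.generate_walks(assoc, cfg.walk)
    degrees = dict(assoc.degree())
    emb = similarity.train_node_embeddings(
        walks,
        dim=cfg.embed_dim,
        window=cfg.window,
        negatives=cfg.sg_negatives,
        epochs=cfg.sg_epochs,
        seed=derive_seed(cfg.seed, "sgns"),
        degrees=degrees,
    )
    sims = {}
    for t in ("lnc", "mi", "mr"):
        net = similarity.cosine_similarity_matrix(emb, graph.nodes[t])
        sims[t] = similarity.assemble_rna_similarity(net)

    dis = list(graph.nodes["dis"])
    rnas = graph.nodes["lnc"] + graph.nodes["mi"] + graph.nodes["mr"]
    rna_pos = {n: i for i, n in enumerate(rnas)}
    profiles = np.zeros((len(dis), len(rnas)))
    dis_pos = {d: i for i, d in enumerate(dis)}
    for rel in ("lnc-dis", "mi-dis", "mr-dis"):
        for a, b in graph.edges[rel]:
            profiles[dis_pos[b], rna_pos[a]] = 1.0
    if profiles.sum() == 0:  # degenerate: no associations at all
        profiles[:, 0] = 1.0
    sims["dis"] = similarity.assemble_disease_similarity(dag, profiles, dis)
    return sims


def build_adjacencies(graph: hetnet.HeteroGraph, sims: dict, cfg: ExperimentConfig):
    """Support graph, triangles, attention, and the A_e / A_h matrices."""
    R = hetnet.build_association_matrix(graph)
    support = hetnet.build_support_graph(graph, sims, cfg.tau)
    triangles = hetnet.enumerate_triangles(support)

    if cfg.use_attention:
        feats, params = hogat.random_attention_inputs(
            support.nodes, seed=derive_seed(cfg.seed, "attention")
        )
        attn = hogat.attention_coefficients(feats, support, params)
        attn = hogat.symmetrize_attention(attn)
        attn = hogat.share_triangle_attention(attn, triangles)
        aug = {t: hogat.augment_similarity(sims[t], attn).values for t in sims}
    else:
        attn = {}
        aug = {t: sims[t].values for t in sims}

    A_e = hetnet.build_enhanced_adjacency(R, aug)
    if cfg.use_higher_order:
        h_blocks = hetnet.higher_order_blocks(triangles, graph)
        A_h = hetnet.build_higher_order_adjacency(R, h_blocks)
    else:
        import scipy.sparse as sp

        A_h = hetnet.BlockMatrix(sp.eye(graph.n_nodes, format="csr"), R.slices)
    A_e = hetnet.normalize_adjacency(A_e, cfg.normalize)
    A_h = hetnet.normalize_adjacency(A_h, cfg.normalize)
    return {"R": R, "support": support, "triangles": triangles, "attn": attn,
            "A_e": A_e, "A_h": A_h}


def split_positives(positives, train_ratio: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    n_train = int(round(train_ratio * len(positives)))
    train = [positives[i] for i in order[:n_train]]
    test = [positives[i] for i in order[n_train:]]
    return train, test


def _random_negatives(graph, positives, n, seed, exclude=None):
    """Baseline sampler: uniform valid triplet x uniform disease."""
    rng = np.random.default_rng(seed)
    lnc_partners: dict = {}
    mr_partners: dict = {}
    for a, b in sorted(graph.edges["lnc-mi"]):
        lnc_partners.setdefault(b, []).append(a)
    for a, b in sorted(graph.edges["mi-mr"]):
        mr_partners.setdefault(a, []).append(b)
    mis = sorted(set(lnc_partners) & set(mr_partners))
    dis = list(graph.nodes["dis"])
    forbidden = {(p.lnc, p.mi, p.mr, p.dis) for p in positives}
    if exclude:
        forbidden |= {(e.lnc, e.mi, e.mr, e.dis) for e in exclude}
    out, chosen = [], set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise sampling.SamplerExhaustedError(n, len(out), attempts - 1)
        m = mis[rng.integers(len(mis))]
        l = lnc_partners[m][rng.integers(len(lnc_partners[m]))]
        r = mr_partners[m][rng.integers(len(mr_partners[m]))]
        d = dis[rng.integers(len(dis))]
        key = (l, m, r, d)
        if key in forbidden or key in chosen:
            continue
        chosen.add(key)
        out.append(sampling.TripletSample(l, m, r, d, 0))
    return out


def draw_negatives(graph, positives, n, cfg: ExperimentConfig, seed, exclude=None):
    if cfg.neg_strategy == "high_order":
        return sampling.sample_negatives(
            positives,
            sorted(graph.edges["lnc-mi"]),
            sorted(graph.edges["mi-mr"]),
            graph.nodes["dis"],
            n,
            seed=seed,
            exclude=exclude,
        )
    if cfg.neg_strategy == "random":
        return _random_negatives(graph, positives, n, seed, exclude=exclude)
    raise ValueError(f"unknown negative strategy {cfg.neg_strategy!r}")


def samples_to_indices(samples, node_index: dict) -> np.ndarray:
    return np.array(
        [[node_index[s.lnc], node_index[s.mi], node_index[s.mr], node_index[s.dis]]
         for s in samples],
        dtype=int,
    ).reshape(-1, 4)


# ---------------------------------------------------------------------------
# experiments


def run_experiment(
    cfg: ExperimentConfig,
    bundle: BenchmarkBundle | None = None,
    permute_labels: bool = False,
    precomputed_sims: dict | None = None,
) -> ExperimentResult:
    """One full train/evaluate cycle.

    ``permute_labels`` shuffles the training labels (a signal-destroying
    control: held-out performance should collapse to chance).
    ``precomputed_sims`` lets ablation sweeps reuse the similarity stage,
    which does not depend on the ablation switches.
    """
    if bundle is None:
        bundle = generate_benchmark(cfg.synth)
    train_pos, test_pos = split_positives(
        bundle.positives, cfg.train.train_ratio, derive_seed(cfg.seed, "split")
    )
    g_train = training_graph(bundle, train_pos)
    sims = precomputed_sims if precomputed_sims is not None else compute_similarities(
        g_train, bundle.dag, cfg
    )
    adj = build_adjacencies(g_train, sims, cfg)

    train_neg = draw_negatives(
        g_train, bundle.positives, len(train_pos), cfg, derive_seed(cfg.seed, "neg-train")
    )
    test_neg = draw_negatives(
        g_train, bundle.positives, len(test_pos), cfg,
        derive_seed(cfg.seed, "neg-test"), exclude=train_neg,
    )

    idx = g_train.node_index()
    tr_pos_i = samples_to_indices(train_pos, idx)
    tr_neg_i = samples_to_indices(train_neg, idx)
    te_pos_i = samples_to_indices(test_pos, idx)
    te_neg_i = samples_to_indices(test_neg, idx)

    if permute_labels:
        all_tr = np.vstack([tr_pos_i, tr_neg_i])
        y = np.concatenate([np.ones(len(tr_pos_i)), np.zeros(len(tr_neg_i))])
        rng = np.random.default_rng(derive_seed(cfg.seed, "permute"))
        y = y[rng.permutation(len(y))]
        tr_pos_i, tr_neg_i = all_tr[y == 1], all_tr[y == 0]

    model = hogcn.train_model(adj["A_e"], adj["A_h"], tr_pos_i, tr_neg_i, cfg.train)

    test_idx = np.vstack([te_pos_i, te_neg_i])
    test_labels = np.concatenate([np.ones(len(te_pos_i)), np.zeros(len(te_neg_i))]).astype(int)

    if cfg.head == "gcn":
        test_scores = model.scores(test_idx)
    else:
        train_idx = np.vstack([tr_pos_i, tr_neg_i])
        y_train = np.concatenate([np.ones(len(tr_pos_i)), np.zeros(len(tr_neg_i))]).astype(int)
        X_train = _embedding_features(model, train_idx)
        X_test = _embedding_features(model, test_idx)
        test_scores = classify.fit_predict_classifier(
            X_train, y_train, X_test, kind=cfg.head, seed=derive_seed(cfg.seed, "head")
        )

    metrics = classify.evaluate(test_scores, test_labels)
    return ExperimentResult(
        metrics=metrics,
        model=model,
        bundle=bundle,
        sims=sims,
        test_samples=test_pos + test_neg,
        test_labels=test_labels,
        test_scores=test_scores,
        extras={"adj": adj, "train_pos": train_pos, "train_neg": train_neg,
                "test_neg": test_neg, "node_index": idx},
    )


def _embedding_features(model: hogcn.TrainedModel, samples_idx: np.ndarray) -> np.ndarray:
    """[h_triplet | h_disease] rows from a trained model's embeddings."""
    H = model.H
    t = np.stack([
        hogcn.triplet_embedding(H[l], H[m], H[r], model.params,
                                leaky_slope=model.cfg.leaky_slope)
        for l, m, r in samples_idx[:, :3]
    ])
    return classify.assemble_features(t, H[samples_idx[:, 3]])


def repeated_holdout(cfg: ExperimentConfig, n_repeats: int = 30,
                     bundle: BenchmarkBundle | None = None) -> dict:
    """Mean +/- std of every metric over repeated random holdout splits."""
    if bundle is None:
        bundle = generate_benchmark(cfg.synth)
    sims = None
    reports = []
    for rep in range(n_repeats):
        c = cfg.reseeded(derive_seed(cfg.seed, f"rep{rep}"))
        res = run_experiment(c, bundle=bundle, precomputed_sims=sims)
        reports.append(res.metrics)
    table = {k: np.array([getattr(r, k) for r in reports])
             for k in ("auc_roc", "auc_pr", "accuracy", "precision", "recall", "f1")}
    return {
        "reports": reports,
        "mean": {k: float(v.mean()) for k, v in table.items()},
        "std": {k: float(v.std(ddof=1)) for k, v in table.items()},
    }


def cross_validate(cfg: ExperimentConfig, k: int = 5, mode: str = "random",
                   bundle: BenchmarkBundle | None = None) -> dict:
    """k-fold CV over positives (random or disease-stratified folds).

    Per fold: the training graph and model see only the training folds'
    positives; negatives are drawn per fold.  In stratified mode the test
    fold's diseases never occur in training (cold-start protocol).
    """
    if bundle is None:
        bundle = generate_benchmark(cfg.synth)
    folds = classify.make_folds(bundle.positives, k, mode=mode,
                                seed=derive_seed(cfg.seed, "folds"))
    rows = []
    for f in range(k):
        tr = [bundle.positives[i] for i in folds.train_indices(f)]
        te = [bundle.positives[i] for i in folds.test_indices(f)]
        if mode == "disease_stratified":
            tr_dis = {p.dis for p in tr}
            te_dis = {p.dis for p in te}
            assert not (tr_dis & te_dis), "disease leaked across folds"
        if not te:
            continue
        g_train = training_graph(bundle, tr)
        c = cfg.reseeded(derive_seed(cfg.seed, f"fold{f}"))
        sims = compute_similarities(g_train, bundle.dag, c)
        adj = build_adjacencies(g_train, sims, c)
        train_neg = draw_negatives(g_train, bundle.positives, len(tr), c,
                                   derive_seed(c.seed, "neg-train"))
        test_neg = draw_negatives(g_train, bundle.positives, len(te), c,
                                  derive_seed(c.seed, "neg-test"), exclude=train_neg)
        idx = g_train.node_index()
        model = hogcn.train_model(
            adj["A_e"], adj["A_h"],
            samples_to_indices(tr, idx), samples_to_indices(train_neg, idx), c.train,
        )
        test_idx = np.vstack([samples_to_indices(te, idx),
                              samples_to_indices(test_neg, idx)])
        labels = np.concatenate([np.ones(len(te)), np.zeros(len(test_neg))]).astype(int)
        report = classify.evaluate(model.scores(test_idx), labels)
        for metric, value in report.as_dict().items():
            rows.append({"fold": f, "metric": metric, "value": value})
    return {"folds": folds, "rows": rows}
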