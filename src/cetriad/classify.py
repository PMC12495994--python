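"""Classifier head, metrics, cross-validation and network diagnostics.

The boosted-tree head (LightGBM) or a logistic regression consumes the
concatenation of the triplet and disease embeddings.  Metrics follow the
ranking definitions exactly: AUC-ROC is the Mann-Whitney probability that
a random positive outranks a random negative (ties count one half),
AUC-PR is the step-wise precision-recall integral, and the operating
threshold is the one maximizing F1 unless supplied.  Disease-stratified
folds implement the cold-start protocol: no disease ever appears in more
than one fold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "MetricsReport",
    "FoldAssignment",
    "assemble_features",
    "fit_predict_classifier",
    "auc_roc",
    "auc_pr",
    "evaluate",
    "make_folds",
    "fold_similarity_analysis",
    "topology_metrics",
    "welch_significance",
    "rank_predictions",
]


@dataclass
class MetricsReport:
    auc_roc: float
    auc_pr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldAssignment:
    """sample position -> fold index, plus the mode and k used."""

    folds: np.ndarray
    mode: str
    k: int
    diseases: list  # per-sample disease ids (needed for stratified checks)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.folds == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.folds != fold)[0]


def assemble_features(h_triplets: np.ndarray, h_diseases: np.ndarray) -> np.ndarray:
    """Feature table: [h_triplet | h_disease] per sample, width 2d."""
    h_triplets = np.atleast_2d(np.asarray(h_triplets, float))
    h_diseases = np.atleast_2d(np.asarray(h_diseases, float))
    if h_triplets.shape != h_diseases.shape:
        raise ValueError("triplet / disease embedding blocks differ in shape")
    X = np.hstack([h_triplets, h_diseases])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def fit_predict_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    kind: str = "gbt",
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 6,
    learning_rate: float = 0.05,
) -> np.ndarray:
    """Fit the final head and score the test rows (probabilities in [0,1])."""
    y_train = np.asarray(y_train, int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if kind == "gbt":
        import lightgbm as lgb

        clf = lgb.LGBMClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            verbosity=-1,
        )
    elif kind == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        clf = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X_train, y_train)
    return clf.predict_proba(X_test)[:, 1]


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-formula AUC: P(score_pos > score_neg) with ties counting 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_pr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise precision-recall integration (no interpolation).

    Equivalent to the average-precision sum  sum_k (R_k - R_{k-1}) P_k
    over descending score order, with ties processed as a block.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUC-PR undefined with a single class")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # collapse ties on the score so a tie block moves as one step
    area, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(area)


def evaluate(scores, labels, threshold: float | None = None) -> MetricsReport:
    """Full metrics report; picks the F1-maximizing threshold if none given."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics undefined with a single class")
    roc = auc_roc(scores, labels)
    pr = auc_pr(scores, labels)
    if threshold is None:
        best_f1, threshold = -1.0, 0.5
        for th in np.unique(scores):
            pred = scores >= th
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            fn = n_pos - tp
            f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            if f1 > best_f1:
                best_f1, threshold = f1, float(th)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = n_pos - tp
    tn = n_neg - fp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_pos
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(
        auc_roc=roc,
        auc_pr=pr,
        accuracy=(tp + tn) / len(labels),
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=float(threshold),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def make_folds(samples, k: int, mode: str = "random", seed: int = 0) -> FoldAssignment:
    """Partition samples into k folds.

    mode="random": a shuffled near-equal split.  mode="disease_stratified":
    diseases are packed into k groups greedy largest-first by sample
    count, and every sample follows its disease — so train and test
    disease sets never overlap (cold-start protocol).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    diseases = [s.dis if hasattr(s, "dis") else s[3] for s in samples]
    n = len(diseases)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if mode == "random":
        order = rng.permutation(n)
        for pos, idx in enumerate(order):
            folds[idx] = pos % k
    elif mode == "disease_stratified":
        counts = Counter(diseases)
        if len(counts) < k:
            raise ValueError(f"only {len(counts)} distinct diseases for k={k}")
        # greedy largest-first bin packing, ties broken by disease id
        loads = [0] * k
        assign: dict = {}
        items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        for d, c in items:
            g = int(np.argmin(loads))
            assign[d] = g
            loads[g] += c
        folds = np.array([assign[d] for d in diseases])
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldAssignment(folds=folds, mode=mode, k=k, diseases=diseases)


def fold_similarity_analysis(sim, folds: FoldAssignment) -> dict:
    """Distributions of disease-pair similarity within vs. across folds.

    ``sim`` is the disease SimilarityMatrix; the fold of a disease is the
    fold its samples sit in (stratified mode guarantees uniqueness).
    Returns the two distributions plus their means.
    """
    disease_fold: dict = {}
    for d, f in zip(folds.diseases, folds.folds):
        if d in disease_fold and disease_fold[d] != f:
            raise ValueError(f"disease {d!r} occurs in several folds")
        disease_fold[d] = int(f)
    ds = sorted(disease_fold)
    intra, inter = [], []
    for a in range(len(ds)):
        for b in range(a + 1, len(ds)):
            v = sim.loc(ds[a], ds[b])
            (intra if disease_fold[ds[a]] == disease_fold[ds[b]] else inter).append(v)
    intra, inter = np.array(intra), np.array(inter)
    return {
        "intra": intra,
        "inter": inter,
        "mean_intra": float(intra.mean()) if intra.size else float("nan"),
        "mean_inter": float(inter.mean()) if inter.size else float("nan"),
    }


def topology_metrics(graph: nx.Graph) -> dict:
    """Network-level means of eigenvector, closeness and degree centrality.

    Eigenvector centrality is the L2-normalized principal eigenvector
    (power iteration); closeness uses the component-normalized
    (Wasserman-Faust) variant so disconnected graphs stay comparable.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least two nodes")
    try:
        ev = nx.eigenvector_centrality(graph, max_iter=1000, tol=1e-8)
    except nx.PowerIterationFailedConvergence:
        ev = nx.eigenvector_centrality_numpy(graph)
    cl = nx.closeness_centrality(graph, wf_improved=True)
    dc = nx.degree_centrality(graph)
    return {
        "aec": float(np.mean(list(ev.values()))),
        "acc": float(np.mean(list(cl.values()))),
        "adc": float(np.mean(list(dc.values()))),
    }


def welch_significance(a, b) -> tuple:
    """Welch's unequal-variance t-test (two-sided).

    Degrees of freedom by Welch-Satterthwaite.  If both groups have zero
    variance and equal means the test is vacuous: (0.0, 1.0).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two runs per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def rank_predictions(scored_candidates, k: int, disease=None) -> list:
    """Top-k candidate (triplet, disease, score) rows.

    Descending by score, ties broken lexicographically on the ids; the
    caller must already have excluded training positives.  ``disease``
    restricts the ranking to one disease.
    """
    rows = [
        (tuple(c[0]), c[1], float(c[2]))
        for c in scored_candidates
        if disease is None or c[1] == disease
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows[: max(k, 0)]
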