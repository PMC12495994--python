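"""Metrics, folds, topology diagnostics and the classifier head."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from cetriad.classify import (
    assemble_features,
    auc_pr,
    auc_roc,
    evaluate,
    fit_predict_classifier,
    fold_similarity_analysis,
    make_folds,
    rank_predictions,
    topology_metrics,
    welch_significance,
)
from cetriad.sampling import TripletSample
from cetriad.similarity import SimilarityMatrix


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFeatures:
    def test_concatenation_layout(self):
        X = assemble_features([[1.0, 2.0]], [[3.0, 4.0]])
        assert np.array_equal(X, [[1, 2, 3, 4]])

    def test_empty_table(self):
        X = assemble_features(np.empty((0, 2)), np.empty((0, 2)))
        assert X.shape == (0, 4)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        t, d = rng.random((5, 3)), rng.random((5, 3))
        perm = rng.permutation(5)
        assert np.array_equal(assemble_features(t, d)[perm],
                              assemble_features(t[perm], d[perm]))


class TestClassifierHead:
    @pytest.mark.parametrize("kind", ["gbt", "logistic"])
    def test_separable_features_give_auc_one(self, kind):
        rng = np.random.default_rng(0)
        X0 = rng.normal(-3, 0.3, size=(60, 4))
        X1 = rng.normal(3, 0.3, size=(60, 4))
        X = np.vstack([X0, X1])
        y = np.array([0] * 60 + [1] * 60)
        scores = fit_predict_classifier(X, y, X, kind=kind, seed=0)
        assert auc_roc(scores, y) == 1.0

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.random((120, 4))
            y = np.array([0, 1] * 60)
            y = y[r.permutation(120)]
            s = fit_predict_classifier(X[:80], y[:80], X[80:], kind="logistic", seed=seed)
            aucs.append(auc_roc(s, y[80:]))
        assert 0.4 < float(np.mean(aucs)) < 0.6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.random((60, 4))
        y = np.array([0, 1] * 30)
        a = fit_predict_classifier(X, y, X, kind="gbt", seed=3)
        b = fit_predict_classifier(X, y, X, kind="gbt", seed=3)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_classifier(np.ones((5, 2)), np.ones(5), np.ones((2, 2)))


class TestEvaluate:
    def test_perfect_and_inverted_ranking(self):
        labels = np.array([1, 1, 0, 0])
        assert auc_roc([0.9, 0.8, 0.2, 0.1], labels) == 1.0
        assert auc_roc([0.1, 0.2, 0.8, 0.9], labels) == 0.0

    def test_worked_pair_counting_example(self):
        assert auc_roc([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 201))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_auc_pr_against_step_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        # oracle: average precision = sum over positives of precision@rank
        order = np.argsort(-scores)
        y = labels[order]
        tp, area = 0, 0.0
        for k, yk in enumerate(y, 1):
            if yk:
                tp += 1
                area += tp / k
        assert auc_pr(scores, labels) == pytest.approx(area / labels.sum())

    def test_threshold_selection_maximizes_f1(self):
        scores = np.array([0.9, 0.7, 0.6, 0.4, 0.2])
        labels = np.array([1, 1, 0, 1, 0])
        report = evaluate(scores, labels)
        for th in np.unique(scores):
            pred = scores >= th
            tp = np.sum(pred & (labels == 1))
            fp = np.sum(pred & (labels == 0))
            fn = labels.sum() - tp
            f1 = 2 * tp / (2 * tp + fp + fn)
            assert report.f1 >= f1 - 1e-12
        assert 0 <= report.accuracy <= 1

    def test_fixed_threshold_respected(self):
        report = evaluate([0.9, 0.1], [1, 0], threshold=0.55)
        assert report.threshold == 0.55
        assert report.accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.5, 0.6], [1, 1])


class TestFolds:
    def samples(self, disease_counts):
        out = []
        for d, c in disease_counts.items():
            out += [TripletSample("l", "m", "r", d, 1)] * c
        return out

    def test_random_folds_near_equal(self):
        folds = make_folds(self.samples({"d1": 50, "d2": 50}), k=5, mode="random", seed=0)
        sizes = np.bincount(folds.folds, minlength=5)
        assert np.all(sizes == 20)

    def test_stratified_keeps_diseases_whole(self):
        s = self.samples({"a": 5, "b": 4, "c": 3, "d": 2})
        folds = make_folds(s, k=2, mode="disease_stratified", seed=0)
        for d in "abcd":
            fold_set = {f for f, dd in zip(folds.folds, folds.diseases) if dd == d}
            assert len(fold_set) == 1

    def test_greedy_balance_matches_enumeration(self):
        s = self.samples({"a": 10, "b": 9, "c": 1})
        folds = make_folds(s, k=2, mode="disease_stratified", seed=0)
        loads = np.bincount(folds.folds, minlength=2)
        # optimum over all disease partitions into 2 groups
        best = min(
            max(sum(c for d, c in {"a": 10, "b": 9, "c": 1}.items() if assign[d] == g)
                for g in range(2))
            for assign in (dict(zip("abc", bits))
                           for bits in itertools.product(range(2), repeat=3))
        )
        assert loads.max() == best == 10

    def test_too_few_diseases_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self.samples({"a": 3}), k=2, mode="disease_stratified")

    def test_stratified_disjoint_across_seeds(self, tiny_bundle):
        for seed in range(20):
            folds = make_folds(tiny_bundle.positives, k=3,
                               mode="disease_stratified", seed=seed)
            per_disease = {}
            for f, d in zip(folds.folds, folds.diseases):
                per_disease.setdefault(d, set()).add(int(f))
            assert all(len(v) == 1 for v in per_disease.values())


class TestFoldSimilarity:
    def block_sim(self):
        ids = [f"d{i}" for i in range(6)]
        S = np.full((6, 6), 0.1)
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.9
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(ids, S)

    def folds_for(self, assignment):
        samples = [TripletSample("l", "m", "r", d, 1) for d in assignment]
        return make_folds(samples, k=2, mode="disease_stratified", seed=0)

    def test_block_structure_separates_intra_inter(self):
        sim = self.block_sim()
        samples = [TripletSample("l", "m", "r", f"d{i}", 1) for i in range(6)]
        folds = make_folds(samples, k=2, mode="disease_stratified", seed=0)
        # force folds matching the similarity blocks
        folds.folds = np.array([0, 0, 0, 1, 1, 1])
        out = fold_similarity_analysis(sim, folds)
        assert out["mean_intra"] > out["mean_inter"]

    def test_single_fold_has_empty_inter(self):
        sim = self.block_sim()
        samples = [TripletSample("l", "m", "r", f"d{i}", 1) for i in range(6)]
        folds = make_folds(samples, k=2, mode="random", seed=0)
        folds.folds = np.zeros(6, dtype=int)
        out = fold_similarity_analysis(sim, folds)
        assert out["inter"].size == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"d{i}" for i in range(8)]
        S = rng.random((8, 8))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sim = SimilarityMatrix(ids, S)
        samples = [TripletSample("l", "m", "r", d, 1) for d in ids]
        folds = make_folds(samples, k=3, mode="disease_stratified", seed=1)
        out = fold_similarity_analysis(sim, folds)
        fold_of = dict(zip(folds.diseases, folds.folds))
        intra = [S[i, j] for i in range(8) for j in range(i + 1, 8)
                 if fold_of[ids[i]] == fold_of[ids[j]]]
        inter = [S[i, j] for i in range(8) for j in range(i + 1, 8)
                 if fold_of[ids[i]] != fold_of[ids[j]]]
        assert sorted(out["intra"]) == pytest.approx(sorted(intra))
        assert sorted(out["inter"]) == pytest.approx(sorted(inter))


class TestTopology:
    def test_complete_graph_degree_centrality(self):
        assert topology_metrics(nx.complete_graph(4))["adc"] == pytest.approx(1.0)

    def test_star_graph_degree_centrality(self):
        assert topology_metrics(nx.star_graph(3))["adc"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            got = topology_metrics(g)
            nodes = sorted(g.nodes)
            # degree centrality oracle
            adc = np.mean([g.degree(v) / (n - 1) for v in nodes])
            assert got["adc"] == pytest.approx(adc)
            # closeness (component-normalized) oracle via BFS
            cls = []
            for v in nodes:
                dist = nx.single_source_shortest_path_length(g, v)
                tot = sum(dist.values())
                if tot > 0:
                    r = len(dist) - 1
                    cls.append((r / (n - 1)) * (r / tot))
                else:
                    cls.append(0.0)
            assert got["acc"] == pytest.approx(np.mean(cls))
            # eigenvector centrality oracle on connected graphs
            if nx.is_connected(g):
                B = nx.to_numpy_array(g, nodelist=nodes)
                w, V = np.linalg.eigh(B)
                v = np.abs(V[:, np.argmax(w)])
                v /= np.linalg.norm(v)
                assert got["aec"] == pytest.approx(float(v.mean()), abs=1e-5)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology_metrics(nx.Graph())


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_significance([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        t, p = welch_significance([0.9, 0.91, 0.92], [0.7, 0.71, 0.72])
        assert p < 0.01
        var = np.var([0.9, 0.91, 0.92], ddof=1)
        assert t == pytest.approx(0.2 / np.sqrt(2 * var / 3))

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 12)))
            t, p = welch_significance(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            welch_significance([0.5], [0.4, 0.5])


class TestRank:
    def cands(self):
        return [(("l1", "m1", "r1"), "d1", 0.9),
                (("l2", "m2", "r2"), "d2", 0.9),
                (("l1", "m1", "r2"), "d1", 0.5)]

    def test_k_larger_than_candidates(self):
        out = rank_predictions(self.cands(), k=10)
        assert len(out) == 3
        assert out[0][2] >= out[1][2] >= out[2][2]

    def test_ties_broken_lexicographically(self):
        out = rank_predictions(self.cands(), k=2)
        assert out[0][0] == ("l1", "m1", "r1")
        assert out[1][0] == ("l2", "m2", "r2")

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        cands = [((f"l{i}", f"m{i}", f"r{i}"), f"d{i%3}", float(rng.random()))
                 for i in range(40)]
        out = rank_predictions(cands, k=15)
        full = sorted(cands, key=lambda c: (-c[2], c[0], c[1]))
        assert out == [(tuple(c[0]), c[1], c[2]) for c in full[:15]]

    def test_disease_filter(self):
        out = rank_predictions(self.cands(), k=5, disease="d1")
        assert all(d == "d1" for _, d, _ in out)
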