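import math

import numpy as np
import pandas as pd
import pytest

import methylens as ml
from methylens import evaluate as ev
from methylens.core import LabelVector, ProbMatrix


class TestFoldPlan:
    def _labels(self, n=100, K=4):
        ids = [f"s{i:03d}" for i in range(n)]
        return LabelVector(ids, [f"C{i % K}" for i in range(n)])

    def test_outer_folds_partition_samples(self):
        y = self._labels()
        plan = ev.make_nested_folds(y, 5, 5, seed=0)
        seen = []
        for o in range(5):
            _, te = plan.outer_split(o)
            seen.extend(te)
        assert sorted(seen) == sorted(y.sample_ids)

    def test_balanced_classes_stratify_exactly(self):
        y = self._labels(100, 4)
        plan = ev.make_nested_folds(y, 5, 5, seed=1)
        for o in range(5):
            _, te = plan.outer_split(o)
            counts = y.subset(te).counts()
            assert all(c == 5 for c in counts.values())

    def test_inner_folds_partition_outer_training_set(self):
        y = self._labels()
        plan = ev.make_nested_folds(y, 5, 5, seed=0)
        for o in range(5):
            tr, _ = plan.outer_split(o)
            held = []
            for i in range(5):
                _, h = plan.inner_split(o, i)
                held.extend(h)
            assert sorted(held) == sorted(tr)

    def test_seed_determinism(self):
        y = self._labels()
        p1 = ev.make_nested_folds(y, 5, 5, seed=3)
        p2 = ev.make_nested_folds(y, 5, 5, seed=3)
        p3 = ev.make_nested_folds(y, 5, 5, seed=4)
        np.testing.assert_array_equal(p1.outer, p2.outer)
        assert not np.array_equal(p1.outer, p3.outer)

    def test_small_class_error_names_class(self):
        ids = [f"s{i}" for i in range(20)]
        y = LabelVector(ids, ["Rare"] * 3 + ["Common"] * 17)
        with pytest.raises(ValueError, match="Rare"):
            ev.make_nested_folds(y, 5, 5)


def _brute_metrics(P, codes, classes):
    n, K = P.shape
    order = np.argsort(classes)
    err = 0.0
    for i in range(n):
        best = min(
            (classes[j] for j in range(K) if P[i, j] == P[i].max())
        )
        err += best != classes[codes[i]]
    brier = sum(
        sum((P[i, k] - (1.0 if k == codes[i] else 0.0)) ** 2 for k in range(K))
        for i in range(n)
    ) / n
    mll = -sum(math.log(min(max(P[i, codes[i]], 1e-15), 1 - 1e-15)) for i in range(n)) / n
    return err / n, brier, mll


class TestComputeMetrics:
    def test_uniform_probs_give_log_k(self):
        n, K = 40, 4
        ids = [f"s{i}" for i in range(n)]
        classes = ["a", "b", "c", "d"]
        pm = ProbMatrix(ids, classes, np.full((n, K), 0.25))
        y = LabelVector(ids, [classes[i % K] for i in range(n)])
        rep = ev.compute_metrics(pm, y)
        assert rep.mlogloss == pytest.approx(math.log(4), abs=1e-12)
        # uniform rows argmax to the lexicographically first class
        assert rep.error == pytest.approx(1 - 10 / 40)

    def test_perfect_one_hot_predictions(self):
        ids = ["s1", "s2", "s3"]
        classes = ["x", "y", "z"]
        v = np.eye(3)
        pm = ProbMatrix(ids, classes, v)
        y = LabelVector(ids, classes)
        rep = ev.compute_metrics(pm, y)
        assert rep.error == 0.0
        assert rep.brier == 0.0
        assert rep.mlogloss <= 3.5e-14

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, K = 30, 5
            P = rng.dirichlet(np.ones(K), size=n)
            codes = rng.integers(0, K, n)
            classes = [f"c{k}" for k in range(K)]
            ids = [f"s{i}" for i in range(n)]
            pm = ProbMatrix(ids, classes, P)
            y = LabelVector(ids, [classes[c] for c in codes])
            rep = ev.compute_metrics(pm, y)
            be, bb, bm = _brute_metrics(P, codes, classes)
            assert rep.error == pytest.approx(be, abs=1e-12)
            assert rep.brier == pytest.approx(bb, abs=1e-12)
            assert rep.mlogloss == pytest.approx(bm, abs=1e-12)

    def test_label_outside_class_set_rejected(self):
        pm = ProbMatrix(["a"], ["x", "y"], np.array([[0.5, 0.5]]))
        y = LabelVector(["a"], ["z"])
        with pytest.raises(ValueError, match="class set"):
            ev.compute_metrics(pm, y)


class TestAggregate:
    def _pm(self, v, classes=("a", "b")):
        return ProbMatrix([f"s{i}" for i in range(len(v))], list(classes), np.asarray(v, float))

    def test_idempotent_on_identical_inputs(self):
        pm = self._pm([[0.7, 0.3], [0.2, 0.8]])
        agg, _ = ev.aggregate_predictions([pm, pm, pm])
        np.testing.assert_allclose(agg.values, pm.values, atol=1e-12)

    def test_tie_broken_lexicographically(self):
        p1 = self._pm([[1.0, 0.0]])
        p2 = self._pm([[0.0, 1.0]])
        agg, labels = ev.aggregate_predictions([p1, p2])
        np.testing.assert_allclose(agg.values, [[0.5, 0.5]])
        assert labels.labels == ["a"]

    def test_mean_is_row_stochastic(self):
        rng = np.random.default_rng(0)
        pms = [self._pm(rng.dirichlet([1, 1, 1], size=10), "abc") for _ in range(4)]
        agg, _ = ev.aggregate_predictions(pms)
        np.testing.assert_allclose(agg.values.sum(axis=1), 1.0, atol=1e-12)

    def test_commutes_with_class_reordering(self):
        rng = np.random.default_rng(1)
        v1, v2 = rng.dirichlet([1, 1, 1], size=8), rng.dirichlet([1, 1, 1], size=8)
        a = self._pm(v1, "abc")
        b = self._pm(v2, "abc")
        agg1, _ = ev.aggregate_predictions([a, b])
        b_perm = b.reorder_classes(["c", "a", "b"])
        agg2, _ = ev.aggregate_predictions([a, b_perm])
        np.testing.assert_allclose(agg1.values, agg2.values, atol=1e-12)

    def test_mismatched_samples_rejected(self):
        a = self._pm([[0.5, 0.5]])
        b = ProbMatrix(["other"], ["a", "b"], np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="sample"):
            ev.aggregate_predictions([a, b])


class TestStratifyByConfidence:
    def test_default_bins_partition(self):
        rng = np.random.default_rng(0)
        n = 1000
        conf = rng.random(n)
        ids = [f"s{i}" for i in range(n)]
        pm = ProbMatrix(ids, ["a", "b"], np.tile([0.6, 0.4], (n, 1)))
        y = LabelVector(ids, ["a"] * n)
        df = ev.stratify_by_confidence(pm, conf, y)
        assert df["n"].sum() == n

    def test_boundary_convention(self):
        ids = ["s1", "s2"]
        pm = ProbMatrix(ids, ["a", "b"], np.tile([0.6, 0.4], (2, 1)))
        y = LabelVector(ids, ["a", "a"])
        df = ev.stratify_by_confidence(pm, np.array([0.7, 0.700001]), y)
        assert df.loc[0, "n"] == 1  # 0.7 in the first (closed) bin
        assert df.loc[1, "n"] == 1  # just above goes to (0.7, 0.8]

    def test_error_decreases_with_confidence_when_noise_does(self):
        rng = np.random.default_rng(2)
        n = 2000
        conf = rng.random(n)
        truth = rng.integers(0, 2, n)
        noise = rng.random(n) < 0.5 * (1 - conf)  # noisier labels at low conf
        observed = np.where(noise, 1 - truth, truth)
        classes = ["a", "b"]
        v = np.zeros((n, 2))
        v[np.arange(n), truth] = 0.9
        v[np.arange(n), 1 - truth] = 0.1
        ids = [f"s{i}" for i in range(n)]
        pm = ProbMatrix(ids, classes, v)
        y = LabelVector(ids, [classes[o] for o in observed])
        df = ev.stratify_by_confidence(pm, conf, y)
        errs = df["error"].tolist()
        assert all(errs[i + 1] < errs[i] for i in range(len(errs) - 1))

    def test_out_of_range_confidence_rejected(self):
        pm = ProbMatrix(["s1"], ["a", "b"], np.array([[0.5, 0.5]]))
        y = LabelVector(["s1"], ["a"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ev.stratify_by_confidence(pm, np.array([1.2]), y)


class TestGroupSmallClasses:
    def test_threshold_rule(self):
        ids = [f"s{i}" for i in range(33)]
        labels = ["A"] * 20 + ["B"] * 10 + ["C"] * 3
        out = ev.group_small_classes(LabelVector(ids, labels))
        counts = out.counts()
        assert counts == {"A": 20, "others": 13}

    def test_no_small_classes_is_noop(self):
        ids = [f"s{i}" for i in range(30)]
        labels = ["A"] * 15 + ["B"] * 15
        out = ev.group_small_classes(LabelVector(ids, labels))
        assert out.labels == labels
        assert "others" not in out.class_names

    def test_all_small_collapses_to_single_class(self):
        ids = [f"s{i}" for i in range(9)]
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = ev.group_small_classes(LabelVector(ids, labels))
        assert set(out.labels) == {"others"}


def _brute_indices(X, codes, K):
    n = len(codes)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    sil = []
    for i in range(n):
        own = [j for j in range(n) if codes[j] == codes[i] and j != i]
        if not own:
            sil.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if codes[j] == k])
            for k in range(K)
            if k != codes[i]
        )
        sil.append((b - a) / max(a, b))
    centroids = np.array([X[codes == k].mean(0) for k in range(K)])
    grand = X.mean(0)
    trB = sum((codes == k).sum() * ((centroids[k] - grand) ** 2).sum() for k in range(K))
    trW = sum(((X[codes == k] - centroids[k]) ** 2).sum() for k in range(K))
    ch = (trB / (K - 1)) / (trW / (n - K))
    S = [np.mean(np.linalg.norm(X[codes == k] - centroids[k], axis=1)) for k in range(K)]
    db = np.mean([
        max(
            (S[k] + S[j]) / np.linalg.norm(centroids[k] - centroids[j])
            for j in range(K) if j != k
        )
        for k in range(K)
    ])
    return float(np.mean(sil)), float(ch), float(db)


class TestInternalIndices:
    def test_hand_computed_davies_bouldin(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        y = LabelVector(list("abcd"), ["A", "A", "B", "B"])
        rep = ev.internal_indices(X, y)
        assert rep.davies_bouldin == pytest.approx(0.2, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, K, d = 25, 3, 4
            X = rng.normal(size=(n, d))
            codes = np.r_[np.arange(K), rng.integers(0, K, n - K)]  # no empty class
            y = LabelVector([f"s{i}" for i in range(n)], [f"c{c}" for c in codes])
            rep = ev.internal_indices(X, y)
            sil, ch, db = _brute_indices(X, codes, K)
            assert rep.silhouette == pytest.approx(sil, abs=1e-10)
            assert rep.calinski_harabasz == pytest.approx(ch, abs=1e-8)
            assert rep.davies_bouldin == pytest.approx(db, abs=1e-10)

    def test_tight_separated_blobs_high_silhouette(self):
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(0, 0.05, size=(30, 2)),
            rng.normal(5, 0.05, size=(30, 2)),
        ])
        y = LabelVector([f"s{i}" for i in range(60)], ["A"] * 30 + ["B"] * 30)
        assert ev.internal_indices(X, y).silhouette >= 0.95

    def test_permuted_labels_destroy_silhouette(self):
        rng = np.random.default_rng(2)
        X = np.vstack([
            rng.normal(0, 0.1, size=(30, 2)),
            rng.normal(5, 0.1, size=(30, 2)),
        ])
        labels = np.array(["A"] * 30 + ["B"] * 30)
        perm = rng.permutation(60)
        y = LabelVector([f"s{i}" for i in range(60)], labels[perm].tolist())
        assert ev.internal_indices(X, y).silhouette <= 0.05

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        y = LabelVector(list("abcd"), ["A"] * 4)
        with pytest.raises(ValueError, match="2 classes"):
            ev.internal_indices(X, y)


class TestClassEnrichment:
    def test_balanced_table_no_association(self):
        ids = [f"s{i}" for i in range(40)]
        y = LabelVector(ids, (["K"] * 10 + ["L"] * 10) * 2)
        subset = set(ids[:20])  # 10 K + 10 L inside, same outside
        df = ev.class_enrichment(subset, y).set_index("class")
        assert df.loc["K", "odds_ratio"] == pytest.approx(1.0)
        assert df.loc["K", "p_value"] == pytest.approx(1.0)

    def test_pure_class_subset_infinite_odds(self):
        ids = [f"s{i}" for i in range(15)]
        y = LabelVector(ids, ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        subset = set(ids[:5])
        df = ev.class_enrichment(subset, y).set_index("class")
        assert math.isinf(df.loc["A", "odds_ratio"])
        assert df.loc["A", "p_value"] < 0.05
        assert df.loc["A", "significant"]

    def test_p_matches_hypergeometric_tail_sum(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 10, 4) + np.array([1, 1, 1, 1])
            n = a + b + c + d
            ids = [f"s{i}" for i in range(n)]
            labels = ["K"] * a + ["L"] * b + ["K"] * c + ["L"] * d
            y = LabelVector(ids, labels)
            subset = set(ids[: a + b])
            df = ev.class_enrichment(subset, y).set_index("class")
            # two-sided Fisher p: sum of hypergeometric outcomes no more
            # likely than the observed table
            rv = hypergeom(n, a + c, a + b)
            support = np.arange(max(0, a + b - (b + d)), min(a + b, a + c) + 1)
            pmf = rv.pmf(support)
            p_expected = pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum()
            assert df.loc["K", "p_value"] == pytest.approx(p_expected, abs=1e-10)

    def test_empty_subset_rejected(self):
        y = LabelVector(["a", "b"], ["A", "B"])
        with pytest.raises(ValueError, match="empty"):
            ev.class_enrichment(set(), y)


class TestNestedCV:
    def test_chance_level_on_null_data(self):
        spec = ml.SynthSpec(n_samples=100, n_features=80, n_classes=4,
                            n_informative=5, delta=0.0, seed=0)
        X, y = ml.gen_methyl_dataset(spec)
        res = ev.run_nested_cv(X, y, {"svm": {"kind": "svm"}}, seed=0)
        err = res.metrics.iloc[0]["error"]
        chance = 1 - max(y.counts().values()) / 100
        assert abs(err - chance) <= 0.15

    def test_separable_data_models_accurate(self):
        spec = ml.SynthSpec(n_samples=150, n_features=200, n_classes=3,
                            n_informative=15, delta=0.35, seed=1)
        X, y = ml.gen_methyl_dataset(spec)
        res = ev.run_nested_cv(
            X, y,
            {"svm": {"kind": "svm"}, "esvm": {"kind": "esvm", "B": 10, "m": 80}},
            {"topvar": {"method": "topvar", "n": 100}},
            seed=0,
        )
        m = res.metrics.set_index("model")
        assert m.loc["svm", "error"] <= 0.05
        assert m.loc["esvm", "error"] <= 0.05

    def test_oof_rows_come_from_foreign_fold(self):
        spec = ml.SynthSpec(n_samples=80, n_features=60, n_classes=2,
                            n_informative=5, delta=0.3, seed=0)
        X, y = ml.gen_methyl_dataset(spec)
        plan = ev.make_nested_folds(y, 4, 3, seed=0)
        res = ev.run_nested_cv(X, y, {"svm": {"kind": "svm"}}, folds=plan, seed=0)
        pm = res.raw[("svm", "all")]
        # retrain fold 0's model and check it reproduces its test rows
        from methylens import classifiers as clf

        tr, te = plan.outer_split(0)
        feats = res.selected_features[("all", 0)]
        model = clf.train_svm(X.subset_samples(tr).subset_features(feats), y.subset(tr))
        expect = model.predict_proba(X.subset_samples(te))
        np.testing.assert_allclose(
            expect.reorder_classes(pm.class_names).values,
            pm.subset(te).values, atol=1e-12,
        )

    def test_precomputed_feature_list_rejected(self):
        spec = ml.SynthSpec(n_samples=40, n_features=30, n_classes=2,
                            n_informative=3, delta=0.3, seed=0)
        X, y = ml.gen_methyl_dataset(spec)
        with pytest.raises(TypeError, match="leakage"):
            ev.run_nested_cv(
                X, y, {"svm": {"kind": "svm"}},
                {"cheat": list(X.feature_ids[:10])}, seed=0,
            )

    def test_calibration_report_shape_and_improvement(self):
        spec = ml.SynthSpec(n_samples=120, n_features=100, n_classes=3,
                            n_informative=10, delta=0.3, seed=0)
        X, y = ml.gen_methyl_dataset(spec)
        plan = ev.make_nested_folds(y, 4, 3, seed=0)
        res = ev.run_nested_cv(
            X, y, {"svm": {"kind": "svm"}}, folds=plan, inner_oof=True, seed=0
        )
        table = ev.calibrate_and_evaluate(res, y, methods=("LR", "MR"), seed=0)
        assert len(table) == 1 * (1 + 2)  # |models| x (1 + |methods|)
        assert set(table["calibration"]) == {"Raw", "LR", "MR"}
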