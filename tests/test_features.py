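import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylens as ml
from methylens import features as ft
from methylens.core import BetaMatrix, LabelVector, ProbeAnnotation

from conftest import planted_feature_dataset


def _annotation(rows):
    df = pd.DataFrame(rows, columns=["probe", "gene", "gene_region", "island_region"])
    return ProbeAnnotation(df.set_index("probe"))


class TestTopVariable:
    def test_direct_ranking(self):
        vals = np.array(
            [[0.5, 0.1, 0.30], [0.5, 0.5, 0.32], [0.5, 0.9, 0.50], [0.5, 0.5, 0.52]]
        )
        X = BetaMatrix(list("abcd"), ["f1", "f2", "f3"], vals)
        fs = ft.select_top_variable(X, 2)
        assert fs.feature_ids == ["f2", "f3"]

    def test_full_selection_is_variance_sorted_permutation(self, small_dataset):
        X, _ = small_dataset
        fs = ft.select_top_variable(X, X.n_features)
        assert sorted(fs.feature_ids) == sorted(X.feature_ids)
        assert all(np.diff(fs.scores) <= 1e-15)

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(0)
        X = BetaMatrix(
            [f"s{i}" for i in range(20)],
            [f"f{j:03d}" for j in range(100)],
            rng.random((20, 100)),
        )
        fs = ft.select_top_variable(X, 100)
        brute = sorted(
            zip(X.feature_ids, X.values.var(axis=0, ddof=1)),
            key=lambda t: (-t[1], t[0]),
        )
        assert fs.feature_ids == [f for f, _ in brute]

    def test_n_too_large_rejected(self, small_dataset):
        X, _ = small_dataset
        with pytest.raises(ValueError):
            ft.select_top_variable(X, X.n_features + 1)


class TestLimmaAnova:
    def test_d0_zero_reduces_to_anova_ranking(self, small_dataset):
        X, y = small_dataset
        fl = ft.select_limma(X, y, 30, d0=0)
        fa = ft.select_anova(X, y, 30)
        assert fl.feature_ids == fa.feature_ids
        np.testing.assert_allclose(fl.scores, fa.scores)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_d0_zero_equals_anova_property(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 18, 12
        X = BetaMatrix(
            [f"s{i}" for i in range(n)], [f"f{j:02d}" for j in range(p)],
            rng.random((n, p)),
        )
        y = LabelVector([f"s{i}" for i in range(n)], [f"C{i % 3}" for i in range(n)])
        assert ft.select_limma(X, y, p, d0=0).feature_ids == ft.select_anova(X, y, p).feature_ids

    def test_shrinkage_tames_zero_within_class_variance(self):
        # one feature is constant within each class: ordinary F infinite
        rng = np.random.default_rng(3)
        n = 8
        vals = rng.random((n, 4))
        vals[:, 0] = [0, 0, 0, 0, 1, 1, 1, 1]
        X = BetaMatrix([f"s{i}" for i in range(n)], list("wxyz"), vals)
        y = LabelVector([f"s{i}" for i in range(n)], ["A"] * 4 + ["B"] * 4)
        fa = ft.select_anova(X, y, 4)
        assert np.isinf(fa.scores[0])
        fl = ft.select_limma(X, y, 4, d0=2.0)
        assert np.isfinite(fl.scores).all()

    def test_single_feature_f_equals_squared_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0.4, 0.1, 10), rng.normal(0.6, 0.1, 10)
        X = BetaMatrix(
            [f"s{i}" for i in range(20)], ["f1"],
            np.concatenate([a, b])[:, None], "generic",
        )
        y = LabelVector(X.sample_ids, ["A"] * 10 + ["B"] * 10)
        F = ft.select_anova(X, y, 1).scores[0]
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_informative_recovery(self):
        hits = 0
        for seed in range(20):
            X, y, informative = planted_feature_dataset(seed)
            sel = set(ft.select_limma(X, y, 10).feature_ids)
            hits += len(sel & informative) >= 9
        assert hits >= 19

    def test_null_data_recovery_at_chance(self):
        # with delta=0 the "informative" features are just 10 of 200 nulls
        overlaps = []
        for seed in range(10):
            X, y, informative = planted_feature_dataset(seed, delta=0.0)
            sel = set(ft.select_anova(X, y, 10).feature_ids)
            overlaps.append(len(sel & informative))
        assert np.mean(overlaps) <= 2.0  # E[overlap] = 0.5 under the null

    def test_class_with_one_sample_rejected(self, small_dataset):
        X, _ = small_dataset
        y = LabelVector(X.sample_ids, ["A"] + ["B"] * (X.n_samples - 1))
        with pytest.raises(ValueError, match="< 2 samples"):
            ft.select_limma(X, y, 5)

    def test_matches_reference_limma_implementation(self, tmp_path):
        """Moderated F agrees with the Bioconductor limma eBayes F."""
        rng = np.random.default_rng(5)
        n, p, K = 24, 60, 3
        sd = np.sqrt(0.02 / rng.gamma(4.0, 0.25, size=p))
        vals = rng.normal(0.5, sd, size=(n, p))
        lab = np.arange(n) % K
        vals[np.ix_(lab == 0, np.arange(5))] += 0.2
        ids = [f"S{i:02d}" for i in range(n)]
        fids = [f"cg{j:03d}" for j in range(p)]
        X = BetaMatrix(ids, fids, vals, "generic")
        y = LabelVector(ids, [f"C{k + 1}" for k in lab])
        pd.DataFrame(vals.T, index=fids, columns=ids).to_csv(tmp_path / "m.tsv", sep="\t")
        pd.DataFrame({"s": ids, "g": y.labels}).to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            X <- as.matrix(read.delim("m.tsv", row.names=1))
            grp <- factor(read.delim("g.tsv")$g)
            design <- model.matrix(~0+grp); colnames(design) <- levels(grp)
            ctr <- makeContrasts(C2-C1, C3-C1, levels=levels(grp))
            fit <- eBayes(contrasts.fit(lmFit(X, design), ctr))
            write.table(data.frame(probe=rownames(X), F=fit$F), "F.tsv",
                        sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        res = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "F.tsv", sep="\t").set_index("probe")["F"]
        fs = ft.select_limma(X, y, p)
        mine = pd.Series(fs.scores, index=fs.feature_ids)
        np.testing.assert_allclose(mine[ref.index], ref, rtol=1e-8)


class TestScmer:
    def test_identity_weights_reproduce_affinities(self, two_cluster_matrix):
        X, _, _ = two_cluster_matrix
        from methylens.features import (
            _scmer_loss_grad,
            _weighted_sqdist,
            perplexity_affinities,
        )

        D2 = _weighted_sqdist(X.values, np.ones(X.n_features))
        P, beta = perplexity_affinities(D2, 20.0)
        loss, _ = _scmer_loss_grad(
            X.values, np.ones(X.n_features), P, beta, 0.0, 0.0, want_grad=False
        )
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_no_feature_dropped_without_l1(self, two_cluster_matrix):
        X, _, _ = two_cluster_matrix
        fs = ft.select_scmer(X, X.n_features, perplexity=20, lam1=0.0, lam2=0.0)
        assert len(fs) == X.n_features

    def test_count_nonincreasing_in_l1(self):
        spec = ml.SynthSpec(
            n_samples=50, n_features=60, n_classes=2, n_informative=5,
            delta=0.35, seed=0,
        )
        X, _ = ml.gen_methyl_dataset(spec)
        counts = [
            len(ft.select_scmer(X, 10, perplexity=15, lam1=l1))
            for l1 in [0.0, 0.002, 0.008, 0.032, 0.128]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_loss_trace_monotone_decreasing(self, two_cluster_matrix):
        X, _, _ = two_cluster_matrix
        fs = ft.select_scmer(X, 10, perplexity=39)
        tr = fs.params["loss_trace"]
        assert all(tr[i + 1] <= tr[i] + 1e-12 for i in range(len(tr) - 1))

    def test_recovers_separating_features(self):
        hits = 0
        for seed in range(8):
            spec = ml.SynthSpec(
                n_samples=120, n_features=100, n_classes=2, n_informative=5,
                delta=0.35, seed=seed,
            )
            X, _ = ml.gen_methyl_dataset(spec)
            sel = set(ft.select_scmer(X, 10, perplexity=39).feature_ids)
            hits += len(sel & set(X.feature_ids[:10])) >= 8
        assert hits >= 7

    def test_too_few_samples_rejected(self):
        X = BetaMatrix(
            [f"s{i}" for i in range(5)], [f"f{j}" for j in range(4)],
            np.random.default_rng(0).random((5, 4)),
        )
        with pytest.raises(ValueError, match="10 samples"):
            ft.select_scmer(X, 2)


class TestAnnotationOps:
    def test_promoter_region_filter(self):
        ann = _annotation(
            [("p1", "G1", "TSS200", "Island"), ("p2", "G2", "Body", "OpenSea")]
        )
        fs = ft.FeatureSet("topvar", ["p1", "p2"], np.array([1.0, 0.5]))
        genes, skipped = ft.map_probes_to_genes(fs, ann)
        assert genes == {"G1"} and skipped == 0

    def test_duplicate_genes_collapse(self):
        ann = _annotation(
            [("p1", "G1", "TSS200", "Island"), ("p2", "G1", "1stExon", "Shore")]
        )
        fs = ft.FeatureSet("topvar", ["p1", "p2"], np.array([1.0, 0.5]))
        genes, _ = ft.map_probes_to_genes(fs, ann)
        assert genes == {"G1"}

    def test_uncovered_probes_counted(self):
        ann = _annotation([("p1", "G1", "TSS200", "Island")])
        fs = ft.FeatureSet("topvar", ["q1", "q2"], np.array([1.0, 0.5]))
        genes, skipped = ft.map_probes_to_genes(fs, ann)
        assert genes == set() and skipped == 2

    def test_pseudo_omics_partition(self):
        rows = [
            ("p1", "G1", "TSS200", "Island"), ("p2", "G2", "TSS1500", "Shore"),
            ("p3", "G3", "Body", "Island"), ("p4", "G4", "Body", "Shelf"),
            ("p5", "", "other", "OpenSea"), ("p6", "", "other", "OpenSea"),
        ]
        ann = _annotation(rows)
        rng = np.random.default_rng(0)
        X = BetaMatrix(["a", "b"], [r[0] for r in rows], rng.random((2, 6)))
        bundle = ft.split_pseudo_omics(X, ann)
        assert bundle["promoter"].feature_ids == ["p1", "p2"]
        assert bundle["body"].feature_ids == ["p3", "p4"]
        assert bundle["other"].feature_ids == ["p5", "p6"]
        all_feats = sum((bundle[o].feature_ids for o in bundle.omic_names), [])
        assert sorted(all_feats) == sorted(X.feature_ids)

    def test_empty_group_rejected(self):
        ann = _annotation([("p1", "G1", "TSS200", "Island"), ("p2", "G2", "1stExon", "Shore")])
        X = BetaMatrix(["a", "b"], ["p1", "p2"], np.random.default_rng(0).random((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            ft.split_pseudo_omics(X, ann)

    def test_group_sizes_match_annotation_counts(self):
        rng = np.random.default_rng(1)
        regions = rng.choice(["TSS200", "TSS1500", "1stExon", "Body", "other"], 100)
        rows = [(f"p{i:03d}", f"G{i}", r, "OpenSea") for i, r in enumerate(regions)]
        ann = _annotation(rows)
        X = BetaMatrix(
            ["a", "b", "c"], [r[0] for r in rows], rng.random((3, 100))
        )
        bundle = ft.split_pseudo_omics(X, ann)
        n_prom = int(np.isin(regions, ["TSS200", "TSS1500", "1stExon"]).sum())
        n_body = int((regions == "Body").sum())
        assert bundle["promoter"].n_features == n_prom
        assert bundle["body"].n_features == n_body
        assert bundle["other"].n_features == 100 - n_prom - n_body
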