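import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import roc_auc_score, silhouette_score

import segscan as ss
from segscan.simulate import FeatureTable


def separable_cohort(seed=0, n=30):
    """Two classes pushed ~10 sigma apart on ten features."""
    return ss.generate_cohort(
        n_per_class=n, n_features=50,
        planted=[(i, 30.0) for i in range(10)],
        noise_sigma=0.35, seed=seed,
    )


class TestVolcano:
    def test_null_cohort_few_significant(self):
        t = ss.generate_cohort(n_per_class=25, n_features=400, seed=0)
        v = ss.volcano(t, "case", "control")
        # joint gate passes at most ~alpha * n features under the null
        assert v.n_significant <= 0.05 * 400

    def test_planted_fc4_detected(self):
        """FC=4 at n=25/group clears the joint gate with high power."""
        hits = 0
        for seed in range(20):
            t = ss.generate_cohort(n_per_class=25, n_features=50,
                                   planted=[(0, 4.0)], seed=seed)
            v = ss.volcano(t, "case", "control")
            hits += bool(v.table["significant"].iloc[0])
        assert hits == 20

    def test_fold_change_gate_blocks_small_effects(self):
        """p tiny but FC inside (2/3, 1.5) -> not significant."""
        rng = np.random.default_rng(0)
        n = 2000  # huge n makes a 1.2-fold shift hyper-significant
        a = rng.normal(1.2, 0.05, size=(n, 1))
        b = rng.normal(1.0, 0.05, size=(n, 1))
        values = pd.DataFrame(np.vstack([a, b]), columns=["f0"],
                              index=[f"s{i}" for i in range(2 * n)])
        labels = pd.Series(["A"] * n + ["B"] * n, index=values.index)
        v = ss.volcano(FeatureTable(values, labels), "A", "B")
        assert v.table["p_value"].iloc[0] < 1e-9
        assert not v.table["significant"].iloc[0]

    def test_zero_variance_feature_flagged_not_significant(self):
        values = pd.DataFrame(
            {"f0": [1.0] * 10, "f1": np.r_[np.ones(5) * 2, np.ones(5)]},
            index=[f"s{i}" for i in range(10)],
        )
        values["f1"] += np.linspace(0, 0.01, 10)  # f1 varies, f0 constant
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=values.index)
        v = ss.volcano(FeatureTable(values, labels), "A", "B")
        assert np.isnan(v.table["p_value"]["f0"])
        assert not v.table["significant"]["f0"]

    def test_fdr_switch_is_more_conservative(self):
        t = ss.generate_cohort(n_per_class=20, n_features=500,
                               planted=[(0, 3.0)], seed=2)
        raw = ss.volcano(t, "case", "control")
        adj = ss.volcano(t, "case", "control", fdr=True)
        assert adj.n_significant <= raw.n_significant

    def test_too_few_samples_rejected(self):
        t = ss.generate_cohort(n_per_class=(1, 5), n_features=5, seed=0)
        with pytest.raises(ValueError):
            ss.volcano(t, "case", "control")


class TestUnsupervised:
    def test_pca_separates_classes(self):
        t = separable_cohort()
        scores, evr = ss.unsupervised(t, "pca", n_components=2)
        y = (t.labels == "case").astype(int)
        assert silhouette_score(scores[["PC1"]], y) > 0.5
        assert evr[0] > evr[1]

    def test_duplicate_samples_merge_at_zero_height(self):
        t = separable_cohort(n=5)
        values = pd.concat([t.values, t.values.iloc[[0]].set_index(
            pd.Index(["dup"]))])
        labels = pd.concat([t.labels, pd.Series(["control"], index=["dup"])])
        Z = ss.unsupervised(FeatureTable(values, labels), "hclust")
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_hclust_recovers_two_groups(self):
        t = separable_cohort()
        Z = ss.unsupervised(t, "hclust")
        assign = fcluster(Z, t.values.shape[0] // 30, criterion="maxclust")
        y = (t.labels == "case").astype(int).values
        agreement = max(np.mean((assign - 1) == y), np.mean((assign - 1) != y))
        assert agreement > 0.95

    def test_kmeans_k1_inertia_is_total_within_variance(self):
        t = separable_cohort(n=10)
        labels, inertia = ss.unsupervised(t, "kmeans", k=1, seed=0)
        X = t.values.values
        assert set(labels) == {0}
        assert inertia == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_kmeans_k_exceeding_samples_rejected(self):
        t = separable_cohort(n=5)
        with pytest.raises(ValueError):
            ss.unsupervised(t, "kmeans", k=100)


class TestRocAuc:
    def test_perfect_scores(self):
        auc, _ = ss.roc_auc([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        auc, _ = ss.roc_auc(s, y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_one_discordant_pair_of_four(self):
        """3 concordant + 1 discordant of 4 pairs -> AUC 0.75 (pair counting)."""
        auc, _ = ss.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints(self):
        _, curve = ss.roc_auc([0.2, 0.9, 0.5], [0, 1, 1])
        assert (curve.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (curve.iloc[-1][["fpr", "tpr"]] == 1).all()

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # coarse -> frequent ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        auc, _ = ss.roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auc == pytest.approx(brute, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestClassifier:
    def test_permuted_labels_near_chance(self):
        t = separable_cohort(seed=4)
        rng = np.random.default_rng(4)
        shuffled = pd.Series(rng.permutation(t.labels.values),
                             index=t.labels.index)
        aucs = [ss.train_classifier(FeatureTable(t.values, shuffled),
                                    seed=s).auc_test for s in range(8)]
        assert 0.2 <= float(np.mean(aucs)) <= 0.8

    def test_single_separating_feature_perfect(self):
        values = pd.DataFrame(
            {"f0": np.r_[np.zeros(20), np.ones(20)],
             "f1": np.abs(np.random.default_rng(0).normal(size=40))},
            index=[f"s{i}" for i in range(40)],
        )
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=values.index)
        rep = ss.train_classifier(FeatureTable(values, labels), seed=0)
        assert rep.auc_train == 1.0
        assert rep.auc_test == 1.0

    def test_stratified_split_preserves_proportions(self):
        t = ss.generate_cohort(n_per_class=(20, 60), n_features=20, seed=0)
        rep = ss.train_classifier(t, seed=0)
        test_labels = t.labels.loc[rep.confidence.index]
        counts = test_labels.value_counts()
        # 20% of each class, within one sample
        assert abs(counts.get("control", 0) - 4) <= 1
        assert abs(counts.get("case", 0) - 12) <= 1

    def test_confidence_is_probability(self):
        rep = ss.train_classifier(separable_cohort(seed=5), seed=5)
        assert ((rep.confidence >= 0.5) & (rep.confidence <= 1.0)).all()

    def test_feature_importance_ranks_planted_features(self):
        """Planted features land in the top 2x planted count (median over seeds)."""
        ranks = []
        for seed in range(5):
            t = ss.generate_cohort(n_per_class=30, n_features=100,
                                   planted=[(i, 2.0) for i in range(5)],
                                   seed=seed)
            rep = ss.train_classifier(t, seed=seed)
            planted_names = list(t.values.columns[:5])
            top = list(rep.feature_importance.index[:10])
            ranks.append(sum(n in top for n in planted_names))
        assert np.median(ranks) >= 4

    def test_small_class_rejected(self):
        t = ss.generate_cohort(n_per_class=(4, 30), n_features=10, seed=0)
        with pytest.raises(ValueError):
            ss.train_classifier(t)

    def test_crossvalidate_deterministic_under_seed(self):
        t = separable_cohort(seed=6)
        assert ss.crossvalidate(t, seed=9) == ss.crossvalidate(t, seed=9)

    def test_crossvalidate_null_near_chance(self):
        t = ss.generate_cohort(n_per_class=25, n_features=30, seed=7)
        mean_auc = float(np.mean(ss.crossvalidate(t, seed=7)))
        assert 0.25 <= mean_auc <= 0.75

    def test_bootstrap_ci_brackets_auc(self):
        t = separable_cohort(seed=8, n=40)
        rep = ss.train_classifier(t, seed=8, with_ci=True)
        lo, hi = rep.auc_test_ci
        assert lo <= rep.auc_test <= hi
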