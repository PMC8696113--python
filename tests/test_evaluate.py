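import numpy as np
import pandas as pd
import pytest

from tred.evaluate import (
    RECEPTOR_STATUS_SCHEME,
    EvaluationReport,
    LabelScheme,
    StratificationError,
    compare_classification_fractions,
    confusion_matrix,
    cross_validate,
    evaluate_pretrained,
    make_fold_plan,
    percent_change,
    regroup_labels,
    roc_auc,
    umap_project,
)

from .conftest import make_separable_positions


class TestFoldPlan:
    def test_balanced_exact_divisibility(self):
        labels = np.repeat(["A", "B"], 500)
        plan = make_fold_plan(labels, k=5, seed=0)
        for trial in plan.trials:
            assert len(trial.test_idx) == 200
            assert (labels[trial.test_idx] == "A").sum() == 100

    def test_partition_property(self, rng):
        labels = rng.choice(["x", "y", "z"], size=143, p=[0.5, 0.3, 0.2])
        plan = make_fold_plan(labels, k=5, seed=1)
        all_test = np.concatenate([t.test_idx for t in plan.trials])
        assert sorted(all_test) == list(range(len(labels)))  # disjoint + exhaustive
        for t in plan.trials:
            assert not set(t.train_idx) & set(t.val_idx)
            assert not set(t.train_idx) & set(t.test_idx)
            assert not set(t.val_idx) & set(t.test_idx)
            assert len(t.train_idx) + len(t.val_idx) + len(t.test_idx) == len(labels)

    def test_unbalanced_proportions_within_one_sample(self, rng):
        labels = np.repeat(["a", "b", "c"], [120, 50, 30])
        plan = make_fold_plan(labels, k=5, seed=2)
        for lab, n in [("a", 120), ("b", 50), ("c", 30)]:
            for t in plan.trials:
                got = (labels[t.test_idx] == lab).sum()
                assert abs(got - n / 5) <= 1

    def test_64_16_20_split_fractions(self):
        labels = np.repeat(["A", "B", "C"], [100, 75, 50])  # divisible by 25
        plan = make_fold_plan(labels, k=5, seed=0)
        n = len(labels)
        for t in plan.trials:
            assert len(t.train_idx) / n == 0.64
            assert len(t.val_idx) / n == 0.16
            assert len(t.test_idx) / n == 0.20

    def test_small_class_raises_naming_it(self):
        labels = np.array(["A"] * 20 + ["rare"] * 3)
        with pytest.raises(StratificationError, match="rare"):
            make_fold_plan(labels, k=5)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        y = ["a", "b", "c"] * 4
        cm = confusion_matrix(y, y, normalize="true-rows")
        np.testing.assert_array_equal(cm.to_numpy(), np.eye(3))

    def test_hand_counted_toy(self):
        raw = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        np.testing.assert_array_equal(raw.to_numpy(), [[1, 1], [0, 2]])
        norm = confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"],
                                normalize="true-rows")
        np.testing.assert_array_equal(norm.to_numpy(), [[0.5, 0.5], [0, 1]])

    def test_random_predictions_near_uniform(self, rng):
        classes = list("ABCDEF")
        true = rng.choice(classes, 6000)
        pred = rng.choice(classes, 6000)
        cm = confusion_matrix(true, pred, normalize="true-rows")
        p = 1 / 6
        sigma = np.sqrt(p * (1 - p) / 1000)
        assert np.all(np.abs(cm.to_numpy() - p) < 3.5 * sigma)

    def test_rows_sum_to_one(self, rng):
        true = rng.choice(list("abc"), 200)
        pred = rng.choice(list("abc"), 200)
        cm = confusion_matrix(true, pred, normalize="true-rows")
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            confusion_matrix(["a"], ["b"], labels=["a"], pred_labels=["a"])


def auc_pairwise_oracle(scores, positives):
    """Brute force over all positive-negative pairs, ties counted 1/2."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_auc_one(self):
        proba = np.array([[0.9, 0.1]] * 5 + [[0.1, 0.9]] * 5)
        labels = ["A"] * 5 + ["B"] * 5
        res = roc_auc(proba, labels, ["A", "B"])
        assert res["A"].auc == 1.0 and res["B"].auc == 1.0

    def test_chance_level_near_half(self, rng):
        n = 4000
        p = rng.uniform(size=n)
        proba = np.column_stack([p, 1 - p])
        labels = rng.choice(["A", "B"], n)
        res = roc_auc(proba, labels, ["A", "B"])
        assert abs(res["A"].auc - 0.5) < 0.03

    def test_matches_pairwise_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, size=18) / 4.0  # forces ties
        labels = np.array(["P" if v else "N" for v in rng.integers(0, 2, 18)])
        if len(set(labels)) < 2:
            labels[0] = "P" if labels[0] == "N" else "N"
        proba = np.column_stack([1 - scores, scores])
        res = roc_auc(proba, labels, ["N", "P"])
        oracle = auc_pairwise_oracle(scores, labels == "P")
        assert res["P"].auc == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_class_flagged(self):
        proba = np.array([[0.6, 0.4], [0.3, 0.7]])
        res = roc_auc(proba, ["A", "A"], ["A", "B"])
        assert res["A"].auc is None and res["B"].auc is None

    def test_invalid_probability_rows_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            roc_auc(np.array([[0.7, 0.7]]), ["A"], ["A", "B"])


class TestLabelScheme:
    def test_receptor_status_mapping(self):
        s = RECEPTOR_STATUS_SCHEME
        assert s.coarse("MCF7") == "HR+"
        assert s.coarse("BT474") == "HER2+"
        assert s.coarse("SKBR3") == "HER2+"
        assert s.coarse("MDA-MB-468") == "TN"
        assert s.coarse("MDA-MB-231") == "TN"
        assert s.coarse("BT549") == "TN"
        assert s.coarse_labels == ["HER2+", "HR+", "TN"]

    def test_regroup_counts_conserved(self):
        fine = np.repeat(
            ["MCF7", "BT474", "SKBR3", "MDA-MB-468", "MDA-MB-231", "BT549"], 100
        )
        coarse = regroup_labels(fine, RECEPTOR_STATUS_SCHEME)
        counts = pd.Series(coarse).value_counts()
        assert counts["HR+"] == 100 and counts["HER2+"] == 200 and counts["TN"] == 300

    def test_regroup_then_count_commutes(self, rng):
        fine = rng.choice(list(RECEPTOR_STATUS_SCHEME.mapping), 300)
        counted_then_grouped = {
            c: sum((fine == f).sum() for f in RECEPTOR_STATUS_SCHEME.fines_of(c))
            for c in RECEPTOR_STATUS_SCHEME.coarse_labels
        }
        grouped = regroup_labels(fine, RECEPTOR_STATUS_SCHEME)
        grouped_then_counted = {
            c: int((grouped == c).sum()) for c in RECEPTOR_STATUS_SCHEME.coarse_labels
        }
        assert counted_then_grouped == grouped_then_counted

    def test_unmapped_label_rejected(self):
        with pytest.raises(KeyError, match="HeLa"):
            regroup_labels(["HeLa"], RECEPTOR_STATUS_SCHEME)


class TestUMAP:
    def test_separated_blobs_stay_separated(self, rng):
        f = np.vstack([
            rng.normal(0, 0.3, size=(40, 8)),
            rng.normal(6, 0.3, size=(40, 8)),
        ])
        labels = np.repeat(["a", "b"], 40)
        coords = umap_project(f, labels, seed=0)
        from sklearn.metrics import silhouette_score

        assert coords.shape == (80, 2)
        assert silhouette_score(coords, labels) > 0.5

    def test_deterministic_given_seed(self, rng):
        f = rng.normal(size=(30, 5))
        a = umap_project(f, seed=9, n_neighbors=10)
        b = umap_project(f, seed=9, n_neighbors=10)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_rows_ok(self, rng):
        f = rng.normal(size=(15, 4))
        f = np.vstack([f, f])
        coords = umap_project(f, seed=0, n_neighbors=8)
        assert np.all(np.isfinite(coords))

    def test_too_few_samples_guidance(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            umap_project(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_project(rng.normal(size=(12, 4)), n_neighbors=15)


class MeanStepClassifier:
    """Threshold-free nearest-centroid stub on mean step length.

    Duck-types the estimator interface so orchestration logic can be
    tested without network training.
    """

    def __init__(self, seed=0):
        self.seed = seed

    @staticmethod
    def _feature(X):
        return np.linalg.norm(np.diff(X, axis=1), axis=2).mean(axis=1)

    def fit(self, X, y, X_val=None, y_val=None):
        f = self._feature(X)
        self.classes_ = np.unique(y)
        self.centroids_ = np.array([f[np.asarray(y) == c].mean() for c in self.classes_])
        return self

    def predict_proba(self, X):
        d = np.abs(self._feature(X)[:, None] - self.centroids_[None, :])
        w = 1.0 / (d + 1e-9)
        return w / w.sum(axis=1, keepdims=True)

    def extract_features(self, X):
        return self._feature(X)[:, None]


class TestCrossValidate:
    def test_pooled_accuracy_equals_recount(self, rng):
        X, y = make_separable_positions(rng, n_per_class=50, length=32,
                                        scales=(0.05, 0.2, 0.8))
        rep = cross_validate(X, y, estimator_factory=lambda f: MeanStepClassifier(),
                             k=5, seed=0, compute_features=True)
        assert rep.accuracy == np.mean(rep.true_labels == rep.predicted_labels)
        raw = rep.confusion_raw.to_numpy()
        assert np.trace(raw) / raw.sum() == pytest.approx(rep.accuracy)
        assert rep.accuracy >= 0.9  # separable classes
        # per-fold matrices sum to the pooled matrix
        total = sum(m.to_numpy() for m in rep.per_fold_confusion)
        np.testing.assert_array_equal(total, raw)

    def test_label_permutation_near_chance(self, rng):
        X, y = make_separable_positions(rng, n_per_class=60, length=32)
        y_perm = rng.permutation(y)
        rep = cross_validate(X, y_perm, estimator_factory=lambda f: MeanStepClassifier(),
                             k=5, seed=0, compute_features=False)
        n = len(y_perm)
        sigma = np.sqrt(0.5 * 0.5 / n)
        assert abs(rep.accuracy - 0.5) < 4 * sigma

    def test_trained_network_recovers_separable_classes(self, rng, tiny_net_kwargs):
        X, y = make_separable_positions(rng, n_per_class=30, length=64,
                                        scales=(0.05, 0.25, 1.0))
        rep = cross_validate(X, y, k=5, seed=0, compute_features=False,
                             **tiny_net_kwargs)
        assert rep.accuracy >= 0.9

    def test_report_row_sums_and_serialization(self, rng, tmp_path):
        X, y = make_separable_positions(rng, n_per_class=25, length=32)
        rep = cross_validate(X, y, estimator_factory=lambda f: MeanStepClassifier(),
                             k=5, seed=0)
        np.testing.assert_allclose(rep.confusion_normalized.sum(axis=1), 1.0, atol=1e-9)
        rep.save(tmp_path / "r.json")
        files = rep.save_tables(tmp_path)
        assert all(p.exists() for p in files)


class TestPretrained:
    def _fitted_stub(self, rng, scales=(0.05, 0.8)):
        X, y = make_separable_positions(rng, n_per_class=40, length=32, scales=scales)
        return MeanStepClassifier().fit(X, y), X, y

    def test_self_consistency_on_training_data(self, rng):
        clf, X, y = self._fitted_stub(rng)
        rep = evaluate_pretrained(clf, X, y)
        recount = np.mean(clf.predict_proba(X).argmax(1) ==
                          np.searchsorted(clf.classes_, y))
        assert rep.accuracy == pytest.approx(recount)

    def test_distribution_shift_raises_target_fraction(self, rng):
        clf, X, y = self._fitted_stub(rng)
        # "perturbed" class0 drifts toward class1's step scale
        X_before, _ = make_separable_positions(rng, n_per_class=60, length=32,
                                               scales=(0.05,))
        X_after, _ = make_separable_positions(rng, n_per_class=60, length=32,
                                              scales=(0.4,))
        lab = np.repeat("class0", 60)
        rep_b = evaluate_pretrained(clf, X_before, lab)
        rep_a = evaluate_pretrained(clf, X_after, lab)
        delta = compare_classification_fractions(rep_b, rep_a)
        assert delta.loc["class1", "fraction_after"] > delta.loc["class1", "fraction_before"]

    def test_unseen_class_contributes_row_not_column(self, rng):
        clf, X, y = self._fitted_stub(rng)
        X_new, _ = make_separable_positions(rng, n_per_class=10, length=32, scales=(0.3,))
        rep = evaluate_pretrained(clf, X_new, np.repeat("benign", 10))
        cm = rep.confusion_raw
        assert "benign" in cm.index and "benign" not in cm.columns
        assert cm.loc["benign"].sum() == 10

    def test_coarse_scheme_regroups_truth(self, rng):
        clf, X, y = self._fitted_stub(rng)
        scheme = LabelScheme(mapping={"class0": "G0", "class1": "G1"})
        rep = evaluate_pretrained(clf, X, y, scheme=scheme)
        assert set(rep.true_labels) == {"G0", "G1"}
        assert list(rep.classes) == ["class0", "class1"]  # predictions stay fine


class TestPercentChange:
    def test_printed_convention(self):
        assert percent_change(0.19, 0.46) == pytest.approx(142.1, abs=0.1)

    def test_sign_of_decrease(self):
        assert percent_change(0.5, 0.39) == pytest.approx(-22.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 0.2)
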