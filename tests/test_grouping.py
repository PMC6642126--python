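import numpy as np
import pytest
from hypothesis import given, strategies as st

import abrgap as ag
from abrgap import GroupLabel


class TestAssignGroup:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.4, GroupLabel.SUPPRESSED),
            (0.5, GroupLabel.SUPPRESSED),  # boundary itself is suppressed
            (0.6, GroupLabel.BALANCED_ENHANCED),
            (2.0, GroupLabel.BALANCED_ENHANCED),
        ],
    )
    def test_boundary_rule(self, ratio, expected):
        assert ag.assign_group(ratio) is expected

    @given(st.floats(min_value=1e-6, max_value=100))
    def test_single_breakpoint_step(self, ratio):
        label = ag.assign_group(ratio)
        expected = GroupLabel.SUPPRESSED if ratio <= 0.5 else GroupLabel.BALANCED_ENHANCED
        assert label is expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ag.assign_group(0.0)


class TestConfusionMatrix:
    def test_perfect_prediction(self):
        ref = [GroupLabel.BALANCED_ENHANCED] * 30 + [GroupLabel.SUPPRESSED] * 96
        cm = ag.confusion_and_informedness(ref, ref)
        assert cm.sensitivity == 1.0
        assert cm.specificity == 1.0
        assert cm.informedness == 1.0

    def test_inverted_prediction(self):
        ref = [GroupLabel.BALANCED_ENHANCED] * 10 + [GroupLabel.SUPPRESSED] * 20
        pred = [
            GroupLabel.SUPPRESSED
            if l is GroupLabel.BALANCED_ENHANCED
            else GroupLabel.BALANCED_ENHANCED
            for l in ref
        ]
        assert ag.confusion_and_informedness(pred, ref).informedness == -1.0

    def test_counts_and_formulas(self):
        # TP=3, FN=1, TN=10, FP=2
        ref = ["balanced_enhanced"] * 4 + ["suppressed"] * 12
        pred = (
            ["balanced_enhanced"] * 3
            + ["suppressed"]
            + ["suppressed"] * 10
            + ["balanced_enhanced"] * 2
        )
        cm = ag.confusion_and_informedness(pred, ref)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (3, 1, 10, 2)
        assert cm.sensitivity == pytest.approx(0.75)
        assert cm.specificity == pytest.approx(10 / 12)
        assert cm.informedness == pytest.approx(0.75 + 10 / 12 - 1)
        assert cm.n == 16

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ag.confusion_and_informedness(["suppressed"], ["suppressed"] * 2)

    def test_informedness_zero_for_random_prediction(self):
        """Label-independent predictions carry no information: the mean
        informedness over many shuffles is ~0."""
        rng = np.random.default_rng(0)
        n = 1000
        ref = np.array(["balanced_enhanced"] * 250 + ["suppressed"] * 750)
        values = []
        for _ in range(1000):
            pred = rng.permutation(ref)
            values.append(ag.confusion_and_informedness(pred, ref).informedness)
        assert abs(np.mean(values)) < 0.05
        assert np.mean(np.abs(values)) < 0.05


class TestClusterToGroup:
    def test_larger_cluster_is_suppressed(self):
        labels = np.array([0] * 96 + [1] * 30)
        groups = ag.cluster_to_group(labels)
        assert groups[:96] == [GroupLabel.SUPPRESSED] * 96
        assert groups[96:] == [GroupLabel.BALANCED_ENHANCED] * 30

    def test_extreme_imbalance(self):
        labels = np.array([0] + [1] * 99)
        groups = ag.cluster_to_group(labels)
        assert groups[0] is GroupLabel.BALANCED_ENHANCED
        assert set(groups[1:]) == {GroupLabel.SUPPRESSED}

    def test_size_tie_uses_feature_magnitude(self):
        labels = np.array([0] * 50 + [1] * 50)
        feats = np.vstack([np.full((50, 2), 0.1), np.full((50, 2), 5.0)])
        groups = ag.cluster_to_group(labels, feats)
        assert groups[0] is GroupLabel.SUPPRESSED  # lower-magnitude cluster
        assert groups[-1] is GroupLabel.BALANCED_ENHANCED
        with pytest.raises(ValueError):
            ag.cluster_to_group(labels)  # tie needs features

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            ag.cluster_to_group(np.array([0, 1, 2]))


class TestKmeansCosine:
    def test_two_directions_separated_exactly(self):
        rng = np.random.default_rng(1)
        a = np.array([1.0, 0.1]) + 0.02 * rng.normal(size=(40, 2))
        b = np.array([-0.5, 1.0]) + 0.02 * rng.normal(size=(25, 2))
        X = np.vstack([a, b])
        labels = ag.kmeans_two(X, seed=0)
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2)) + np.array([2.0, 0.0])
        scales = rng.uniform(0.1, 10.0, size=60)
        base = ag.kmeans_two(X, seed=3)
        scaled = ag.kmeans_two(X * scales[:, None], seed=3)
        # identical partition up to label swap
        assert np.array_equal(base, scaled) or np.array_equal(base, 1 - scaled)

    def test_zero_vector_rejected(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            ag.kmeans_two(X)


class TestSilhouetteSelection:
    @staticmethod
    def _blobs(centers, n=30, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return np.vstack(
            [np.asarray(c) + spread * rng.normal(size=(n, 2)) for c in centers]
        )

    def test_two_blobs_select_two(self):
        X = self._blobs([(1.0, 0.1), (0.1, 1.0)])
        assert ag.silhouette_optimal_k(X, seed=0) == 2

    def test_three_blobs_select_three(self):
        X = self._blobs([(1.0, 0.05), (0.05, 1.0), (-1.0, 0.3)])
        assert ag.silhouette_optimal_k(X, seed=0) == 3

    def test_isotropic_blob_warns(self):
        # a single isotropic cloud has no directional cluster structure:
        # the best silhouette stays weak and triggers the warning flag
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 10))
        with pytest.warns(UserWarning, match="silhouette"):
            ag.silhouette_optimal_k(X, seed=0)

    def test_invalid_k_range_rejected(self):
        X = np.ones((5, 2)) + np.arange(10).reshape(5, 2)
        with pytest.raises(ValueError):
            ag.silhouette_optimal_k(X, k_range=range(2, 11), seed=0)


class TestSvmAndRoc:
    @staticmethod
    def _clouds(n=60, gap=4.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 3))
        b = rng.normal(size=(n, 3)) + gap
        X = np.vstack([a, b])
        y = ["suppressed"] * n + ["balanced_enhanced"] * n
        return X, y

    def test_separable_clouds_classified_perfectly(self):
        X, y = self._clouds()
        report = ag.svm_classify(X, y, seed=0)
        assert report.cv_accuracy_pct == 100.0
        assert report.accuracy_pct == 100.0
        assert report.auc == 1.0
        assert tuple(report.roc_points[0]) == (0.0, 0.0)
        assert tuple(report.roc_points[-1]) == (1.0, 1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 3))
        y = ["suppressed"] * 150 + ["balanced_enhanced"] * 150
        report = ag.svm_classify(X, y, seed=0)
        assert abs(report.cv_accuracy_pct - 50.0) <= 10.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            ag.svm_classify(X, ["suppressed"] * 20)

    def test_roc_perfect_and_reversed(self):
        y = ["suppressed"] * 10 + ["balanced_enhanced"] * 10
        scores = np.concatenate([np.arange(10), np.arange(100, 110)])
        _, auc = ag.roc_auc(scores, y)
        assert auc == 1.0
        _, auc_rev = ag.roc_auc(-scores, y)
        assert auc_rev == 0.0

    def test_roc_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        y = ["suppressed"] * 500 + ["balanced_enhanced"] * 500
        _, auc = ag.roc_auc(rng.normal(size=1000), y)
        assert abs(auc - 0.5) < 0.05

    def test_roc_single_class_rejected(self):
        with pytest.raises(ValueError):
            ag.roc_auc(np.arange(5.0), ["suppressed"] * 5)
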