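"""Feature selection, the alpha1 attention gate, and the multi-class SVM."""

import numpy as np
import pytest

from pacbci.core import ValidationError
from pacbci.select_classify import (FeatureTable, knn_attend, mcfs_select,
                                    sequential_select, svm_predict, svm_train)


def clustered_table(rng, n_per=20, n_clusters=6, n_noise=19, scale=1.0):
    """One feature equal to the cluster indicator plus pure-noise features
    (noise at a quarter of the indicator's unit step)."""
    labels = np.repeat(np.arange(1, n_clusters + 1), n_per)
    n = len(labels)
    informative = labels + 0.1 * rng.standard_normal(n)
    noise = 0.25 * rng.standard_normal((n, n_noise))
    mat = np.column_stack([informative * scale, noise])
    names = ["informative"] + [f"noise{i}" for i in range(n_noise)]
    return FeatureTable(mat, names, labels)


class TestMcfs:
    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = clustered_table(rng)
            sel, _ = mcfs_select(table, n_clusters=6, n_select=1)
            hits += sel[0] == 0
        assert hits >= 48  # >= 95% of 50 seeds

    def test_duplicated_informative_ties_to_lower_index(self):
        rng = np.random.default_rng(3)
        table = clustered_table(rng)
        dup = np.column_stack([table.matrix, table.matrix[:, 0]])
        table2 = FeatureTable(dup, table.names + ["informative_copy"],
                              table.labels)
        sel, scores = mcfs_select(table2, n_clusters=6, n_select=2)
        assert set(sel) == {0, len(table.names)}
        assert sel[0] == 0
        assert scores[0] == pytest.approx(scores[1])

    def test_select_all_ordered_by_score(self):
        rng = np.random.default_rng(1)
        table = clustered_table(rng, n_noise=4)
        sel, scores = mcfs_select(table, n_clusters=6, n_select=5)
        assert len(sel) == 5
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_scaling_invariance_after_standardization(self):
        # standardising first (the documented prerequisite) makes the
        # selection invariant to per-feature rescaling
        rng = np.random.default_rng(5)
        table = clustered_table(rng, n_noise=6)
        scaled = FeatureTable(table.matrix * np.array([7.0] + [0.2] * 6),
                              table.names, table.labels)

        def standardize(t):
            m = (t.matrix - t.matrix.mean(0)) / t.matrix.std(0)
            return FeatureTable(m, t.names, t.labels)

        s1, _ = mcfs_select(standardize(table), 6, 7)
        s2, _ = mcfs_select(standardize(scaled), 6, 7)
        np.testing.assert_array_equal(s1, s2)

    def test_too_many_requested(self):
        rng = np.random.default_rng(0)
        table = clustered_table(rng, n_noise=3)
        with pytest.raises(ValidationError):
            mcfs_select(table, 6, 10)


class TestSequentialSelect:
    def test_separating_feature_selected_first(self):
        rng = np.random.default_rng(2)
        n = 120
        attend = rng.random(n) < 0.5
        alpha = np.where(attend, rng.normal(0.09, 0.02, n),
                         rng.normal(0.06, 0.01, n))
        noise = rng.standard_normal((n, 5))
        table = FeatureTable(np.column_stack([noise[:, :2], alpha,
                                              noise[:, 2:]]),
                             ["n0", "n1", "alpha1_rsp", "n2", "n3", "n4"],
                             attend.astype(int) + 1)
        sel = sequential_select(table, n_select=3)
        assert sel[0] == 2

    def test_noise_only_stops_after_one(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([1, 2], 40)
        table = FeatureTable(rng.standard_normal((80, 6)),
                             [f"n{i}" for i in range(6)], labels)
        sel = sequential_select(table, n_select=6)
        assert len(sel) <= 2  # greedy gains on noise stall immediately

    def test_zero_request_empty(self):
        rng = np.random.default_rng(0)
        table = clustered_table(rng, n_noise=2)
        assert sequential_select(table, n_select=0) == []

    def test_single_class_rejected(self):
        table = FeatureTable(np.zeros((20, 2)), ["a", "b"], np.ones(20))
        with pytest.raises(ValidationError):
            sequential_select(table, 1)


class TestKnnAttend:
    def test_memorized_point(self):
        x = np.array([[0.09], [0.06]])
        y = np.array([True, False])
        assert knn_attend(x, y, np.array([[0.09]]), k=1)[0]

    def test_table3_gaussians_reach_80_percent(self):
        rng = np.random.default_rng(6)
        tr_att = rng.normal(0.09, 0.02, 400)
        tr_non = rng.normal(0.06, 0.01, 400)
        x = np.concatenate([tr_att, tr_non])
        y = np.concatenate([np.ones(400, bool), np.zeros(400, bool)])
        te = np.concatenate([rng.normal(0.09, 0.02, 300),
                             rng.normal(0.06, 0.01, 300)])
        truth = np.concatenate([np.ones(300, bool), np.zeros(300, bool)])
        pred = knn_attend(x, y, te, k=5)
        assert np.mean(pred == truth) >= 0.80

    def test_k1_perfect_on_own_training_set(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((50, 1))
        y = rng.random(50) < 0.5
        assert np.array_equal(knn_attend(x, y, x, k=1), y)

    def test_even_k_rejected(self):
        with pytest.raises(ValidationError):
            knn_attend(np.zeros((4, 1)), np.zeros(4, bool),
                       np.zeros((1, 1)), k=2)

    def test_k_exceeding_train_rejected(self):
        with pytest.raises(ValidationError):
            knn_attend(np.zeros((3, 1)), np.zeros(3, bool),
                       np.zeros((1, 1)), k=5)


class TestSvm:
    def test_separable_toy(self):
        table = FeatureTable(np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]]),
                             ["x", "y"], np.array([1, 1, 2, 2]))
        model = svm_train(table)
        assert np.array_equal(svm_predict(model, table), table.labels)

    def test_three_sigma_classes_cv(self):
        # each class elevates its own coupling-pair column by 3 sigma,
        # replicated over three sensors (as multi-channel PAC features are)
        rng = np.random.default_rng(8)
        labels = np.repeat(np.arange(1, 7), 30)
        onehot = np.eye(6)[labels - 1]
        x = np.tile(3.0 * onehot, 3) + rng.standard_normal((180, 18))
        names = [f"pair{p}@ch{c}" for c in range(3) for p in range(6)]
        table = FeatureTable(x, names, labels)
        from sklearn.model_selection import StratifiedKFold
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True,
                                      random_state=0).split(x, labels):
            m = svm_train(table.subset(rows=tr))
            accs.append(np.mean(svm_predict(m, table.subset(rows=te))
                                == labels[te]))
        assert np.mean(accs) >= 0.95

    def test_predict_aligns_columns_by_name(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((40, 3))
        labels = 1 + (x[:, 0] > 0)
        table = FeatureTable(x, ["a", "b", "c"], labels)
        model = svm_train(table)
        permuted = FeatureTable(x[:, [2, 0, 1]], ["c", "a", "b"], labels)
        np.testing.assert_array_equal(svm_predict(model, permuted),
                                      svm_predict(model, table))

    def test_unknown_feature_at_predict(self):
        table = FeatureTable(np.zeros((10, 2)), ["a", "b"],
                             np.array([1] * 5 + [2] * 5))
        model = svm_train(table)
        other = FeatureTable(np.zeros((3, 2)), ["a", "z"], np.ones(3))
        with pytest.raises(ValidationError):
            svm_predict(model, other)
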