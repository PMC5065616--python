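"""Normalization, forests, partitions, metrics, nested CV."""

import numpy as np
import pandas as pd
import pytest

import nephroscreen as ns
from nephroscreen.classify import make_partitions, _xy


def _tiny_matrix(rng, n_features=10, n_toxic=8, n_nontoxic=8, effect=3.0):
    labels = pd.Series(["PTC-toxic"] * n_toxic + ["non-PTC-toxic"] * n_nontoxic,
                       index=[f"C{i}" for i in range(n_toxic + n_nontoxic)])
    values = rng.normal(0, 0.3, size=(n_features, len(labels)))
    values[0, :n_toxic] += effect
    matrix = pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)],
                          columns=labels.index)
    return matrix, labels


class TestNormalization:
    def test_endpoint_mapping(self):
        m = pd.DataFrame([[0.0, 10.0, 5.0]], index=["f"], columns=list("abc"))
        coeff, normed = ns.normalize(m)
        assert normed.loc["f", "a"] == -1.0
        assert normed.loc["f", "b"] == 1.0
        assert normed.loc["f", "c"] == 0.0

    def test_test_values_may_exceed_range(self):
        train = pd.DataFrame([[0.0, 10.0]], index=["f"], columns=["a", "b"])
        coeff, _ = ns.normalize(train)
        test = pd.DataFrame([[20.0]], index=["f"], columns=["z"])
        assert coeff.apply(test).loc["f", "z"] == 3.0

    def test_constant_feature_maps_to_zero(self):
        train = pd.DataFrame([[5.0, 5.0]], index=["f"], columns=["a", "b"])
        coeff, normed = ns.normalize(train)
        assert (normed.loc["f"] == 0.0).all()

    def test_round_trip_and_non_idempotence(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 6)),
                         index=list("xyz"), columns=list("abcdef"))
        coeff, normed = ns.normalize(m)
        back = coeff.invert(normed)
        np.testing.assert_allclose(back.to_numpy(), m.to_numpy(), atol=1e-12)
        twice = coeff.apply(normed)
        assert not np.allclose(twice.to_numpy(), normed.to_numpy())


class TestMetrics:
    def test_identity_holds(self, rng):
        for _ in range(10):
            y = rng.choice(["PTC-toxic", "non-PTC-toxic"], size=12)
            p = rng.choice(["PTC-toxic", "non-PTC-toxic"], size=12)
            if len(set(y)) < 2:
                continue
            m = ns.performance_metrics(y, p)
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2)

    def test_perfect_and_inverted(self):
        y = np.array(["PTC-toxic", "non-PTC-toxic"])
        assert ns.performance_metrics(y, y)["balanced_accuracy"] == 100.0
        assert ns.performance_metrics(y, y[::-1])["balanced_accuracy"] == 0.0


class TestRandomForest:
    def test_separable_data_perfect_training_accuracy(self, rng):
        X = np.r_[np.zeros((5, 1)), np.ones((5, 1))]
        y = np.array(["non-PTC-toxic"] * 5 + ["PTC-toxic"] * 5)
        clf = ns.train_random_forest(X, y, 50, 1, seed=0)
        assert (clf.predict(X) == y).all()

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(size=(16, 5))
        y = np.array(["PTC-toxic", "non-PTC-toxic"] * 8)
        a = ns.train_random_forest(X, y, 60, 2, seed=9).predict(X)
        b = ns.train_random_forest(X, y, 60, 2, seed=9).predict(X)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ns.train_random_forest(np.zeros((4, 2)), np.array(["PTC-toxic"] * 4), 10, 1, 0)

    def test_informative_feature_importance_exceeds_noise(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            matrix, labels = _tiny_matrix(r, n_features=12, effect=3.0)
            X, y = matrix.to_numpy().T, labels.to_numpy()
            clf = ns.train_random_forest(X, y, 150, 3, seed=seed)
            imp = ns.oob_permutation_importance(clf, X, y, seed=seed)
            hits += imp[0] > np.median(imp[1:])
        assert hits >= 9


class TestGridSearch:
    def test_singleton_grid(self, rng):
        matrix, labels = _tiny_matrix(rng)
        X, y = matrix.to_numpy().T, labels.to_numpy()
        cfg = ns.RFConfig(n_tree_grid=(50,), n_trial_grid=(2,))
        assert ns.grid_search(X, y, X, y, cfg, seed=0) == (50, 2)

    def test_tie_breaks_toward_smaller_model(self, rng):
        # perfectly separable: every combination scores 100 -> smallest wins
        X = np.r_[np.zeros((6, 2)), np.ones((6, 2))]
        y = np.array(["non-PTC-toxic"] * 6 + ["PTC-toxic"] * 6)
        cfg = ns.RFConfig(n_tree_grid=(10, 50, 150), n_trial_grid=(1, 2))
        assert ns.grid_search(X, y, X, y, cfg, seed=1) == (10, 1)


class TestPartitions:
    def test_disjoint_and_covering(self, planted_matrix):
        _, matrix, labels = planted_matrix
        for part in make_partitions(labels, 10, trial=0, seed=3):
            part.validate(matrix.columns)  # raises on violation

    def test_deterministic_fold_membership(self, planted_matrix):
        _, matrix, labels = planted_matrix
        a = make_partitions(labels, 10, trial=1, seed=5)
        b = make_partitions(labels, 10, trial=1, seed=5)
        assert [p.test for p in a] == [p.test for p in b]

    def test_stratification_keeps_both_classes_in_folds(self, planted_matrix):
        _, matrix, labels = planted_matrix
        for part in make_partitions(labels, 10, trial=0, seed=0):
            classes = set(labels.loc[part.test])
            assert len(classes) == 2

    def test_duplicate_compound_detected(self):
        part = ns.CVPartition(training=["a", "b"], fs_test=["b"], rf_test=["c"],
                              test=["d"], fold=0, trial=0)
        with pytest.raises(ValueError, match="two partition sets"):
            part.validate(["a", "b", "c", "d"])


class TestNestedCV:
    CFG = ns.RFConfig(n_tree_grid=(100,), n_trial_grid=(3,))

    def test_planted_signal_high_accuracy(self, planted_matrix):
        _, matrix, labels = planted_matrix
        report = ns.nested_cv(matrix, labels, n_folds=5, n_trials=1, seed=0,
                              config=self.CFG)
        assert report.summary["mean_balanced_accuracy"] > 90.0

    def test_permuted_labels_fall_to_chance(self, planted_matrix):
        _, matrix, labels = planted_matrix
        rng = np.random.default_rng(4)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        report = ns.nested_cv(matrix, permuted, n_folds=5, n_trials=2, seed=0,
                              config=self.CFG)
        assert 38.0 <= report.summary["mean_balanced_accuracy"] <= 62.0

    def test_training_accuracy_exceeds_test_on_average(self, planted_matrix):
        spec, matrix, labels = planted_matrix
        noisy = matrix + np.random.default_rng(8).normal(0, 1.5, size=matrix.shape)
        report = ns.nested_cv(noisy, labels, n_folds=5, n_trials=2, seed=2,
                              config=self.CFG)
        s = report.summary
        assert s["mean_training_accuracy"] >= s["mean_balanced_accuracy"]

    def test_normalization_coefficients_use_training_rows_only(self, planted_matrix):
        """Leakage guard: coefficients derived from the training compounds
        differ from coefficients fitted on all compounds."""
        _, matrix, labels = planted_matrix
        part = make_partitions(labels, 5, trial=0, seed=0)[0]
        coeff_train, _ = ns.normalize(matrix[part.training])
        coeff_all, _ = ns.normalize(matrix)
        assert not np.allclose(coeff_train.f_min.to_numpy(),
                               coeff_all.f_min.to_numpy())
        outside = matrix.drop(columns=part.training)
        normed = coeff_train.apply(outside)
        assert (normed.to_numpy().max() > 1.0) or (normed.to_numpy().min() < -1.0)

    def test_report_identity_on_every_row(self, planted_matrix):
        _, matrix, labels = planted_matrix
        report = ns.nested_cv(matrix, labels, n_folds=5, n_trials=1, seed=0,
                              config=self.CFG)
        rows = report.folds.dropna(subset=["sensitivity", "specificity"])
        np.testing.assert_allclose(
            rows["balanced_accuracy"],
            (rows["sensitivity"] + rows["specificity"]) / 2)


class TestSingleFeatureScreen:
    def test_planted_feature_is_best(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            matrix, labels = _tiny_matrix(r, n_features=6, effect=3.0)
            screen = ns.single_feature_screen(
                matrix, labels, n_folds=4, n_trials=1, seed=seed,
                config=ns.RFConfig(n_tree_grid=(50,), n_trial_grid=(1,)))
            hits += screen["balanced_accuracy"].idxmax() == "f0"
        assert hits >= 4

    def test_group_maxima_bounded_below_by_means(self, rng):
        matrix, labels = _tiny_matrix(rng, n_features=6)
        catalog = pd.DataFrame({"name": matrix.index,
                                "marker": ["dna"] * 3 + ["actin"] * 3,
                                "group": ["texture"] * 6,
                                "region": ["cell"] * 6})
        screen = ns.single_feature_screen(
            matrix, labels, catalog=catalog, n_folds=4, n_trials=1, seed=0,
            config=ns.RFConfig(n_tree_grid=(50,), n_trial_grid=(1,)))
        maxima = ns.group_maxima(screen, by="marker")
        means = screen.groupby("marker")["balanced_accuracy"].mean()
        for marker, row in maxima.iterrows():
            assert row["balanced_accuracy"] >= means[row["marker"]] - 1e-9
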