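"""Recursive feature elimination and the GMM/BIC subset selector."""

import numpy as np
import pandas as pd
import pytest

import nephroscreen as ns
from nephroscreen.classify import make_partitions
from nephroscreen.selection import RFESolution, TrajectoryPoint


def _solution(accs, max_size=None):
    """Build a bare trajectory with sizes len(accs)..1 and given accuracies."""
    n = len(accs)
    points = []
    for i, acc in enumerate(accs):
        feats = tuple(f"f{j}" for j in range(n - i))
        points.append(TrajectoryPoint(features=feats, accuracy=float(acc),
                                      importances=pd.Series(1.0, index=feats)))
    return RFESolution(trajectory=points, final_subset=list(points[-1].features))


def _planted(seed, n_features=12, effect=3.0):
    rng = np.random.default_rng(seed)
    labels = pd.Series(["PTC-toxic"] * 10 + ["non-PTC-toxic"] * 10,
                       index=[f"C{i}" for i in range(20)])
    values = rng.normal(0, 0.3, size=(n_features, 20))
    values[0, :10] += effect
    matrix = pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)],
                          columns=labels.index)
    return matrix, labels


CFG = ns.RFConfig(n_tree_grid=(100,), n_trial_grid=(2,))


class TestRFE:
    def test_trajectory_sizes_strictly_decreasing(self):
        matrix, labels = _planted(0)
        part = make_partitions(labels, 4, trial=0, seed=0)[0]
        coeff, _ = ns.normalize(matrix[part.training])
        sol = ns.rfe(coeff.apply(matrix), labels, part, config=CFG, seed=0)
        sizes = sol.sizes
        assert sizes[0] == len(matrix.index) and sizes[-1] == 1
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_informative_feature_survives_to_the_end(self):
        hits = 0
        for seed in range(10):
            matrix, labels = _planted(seed, n_features=2)
            part = make_partitions(labels, 4, trial=0, seed=seed)[0]
            coeff, _ = ns.normalize(matrix[part.training])
            sol = ns.rfe(coeff.apply(matrix), labels, part, config=CFG, seed=seed)
            assert len(sol.trajectory) == 2
            hits += sol.trajectory[-1].features == ("f0",)
        assert hits >= 9

    def test_geometric_step_reaches_one_feature(self):
        matrix, labels = _planted(1, n_features=40)
        part = make_partitions(labels, 4, trial=0, seed=1)[0]
        coeff, _ = ns.normalize(matrix[part.training])
        sol = ns.rfe(coeff.apply(matrix), labels, part, config=CFG, seed=1,
                     step=0.2, tune_every_iteration=False)
        assert sol.sizes[-1] == 1
        assert len(sol.trajectory) < 40

    def test_partition_leakage_is_hard_error(self):
        matrix, labels = _planted(0)
        part = make_partitions(labels, 4, trial=0, seed=0)[0]
        part.fs_test.append(part.training[0])
        with pytest.raises(ValueError):
            ns.rfe(matrix, labels, part, config=CFG, seed=0)


class TestRankFeatures:
    def test_null_feature_importance_near_zero(self):
        rng = np.random.default_rng(0)
        matrix, labels = _planted(0)
        X, y = matrix.to_numpy().T, labels.to_numpy()
        clf = ns.train_random_forest(X, y, 150, 2, seed=0)
        imp = ns.rank_features(clf, X, y, list(matrix.index), seed=0)
        assert abs(imp["f5"]) < 0.1  # pure noise feature
        assert imp["f0"] > imp["f5"]

    def test_importances_finite_for_all_features(self):
        matrix, labels = _planted(3)
        X, y = matrix.to_numpy().T, labels.to_numpy()
        clf = ns.train_random_forest(X, y, 80, 2, seed=3)
        imp = ns.rank_features(clf, X, y, list(matrix.index), seed=3)
        assert np.isfinite(imp.to_numpy()).all()
        assert len(imp) == len(matrix.index)


class TestGMMSelect:
    def test_two_plateau_trajectory_selects_smallest_high_subset(self):
        # sizes 6..1 with accuracies 90,90,90,50,50,50: the high group's
        # smallest subset has 4 features
        sol = _solution([90, 90, 90, 50, 50, 50])
        chosen = ns.gmm_select(sol, seed=0)
        assert len(chosen) == 4

    def test_degenerate_trajectory_returns_single_feature(self):
        sol = _solution([75, 75, 75, 75, 75])
        assert len(ns.gmm_select(sol, seed=0)) == 1

    def test_short_trajectory_rejected(self):
        sol = _solution([80, 70, 60])
        with pytest.raises(ValueError):
            ns.gmm_select(sol)

    def test_bic_matches_closed_form_gaussian_likelihood(self):
        """BIC = -2 L_m + N_d log N_s with N_d = 3K - 1 in one dimension."""
        from sklearn.mixture import GaussianMixture

        acc = np.array([50.0, 51.0, 49.5, 90.0, 91.0, 89.5]).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=0).fit(acc)
        log_lik = gm.score_samples(acc).sum()
        n_d = 3 * 2 - 1
        by_hand = -2.0 * log_lik + n_d * np.log(len(acc))
        assert gm.bic(acc) == pytest.approx(by_hand, rel=1e-12)

    def test_selection_deterministic_given_seed(self):
        accs = [88, 90, 87, 91, 55, 52, 50, 49]
        a = ns.gmm_select(_solution(accs), seed=7)
        b = ns.gmm_select(_solution(accs), seed=7)
        assert a == b


class TestSplineSelect:
    def test_prefers_small_subset_near_the_maximum(self):
        sol = _solution([90, 91, 90, 89, 70, 60, 50, 40])
        chosen = ns.spline_select(sol)
        assert 4 <= len(chosen) <= 8


class TestConsensus:
    def test_identical_fold_solutions_recovered(self):
        sols = []
        for _ in range(3):
            s = _solution([90, 90, 50, 50])
            s.final_subset = ["f0", "f1"]
            sols.append(s)
        subset, avg = ns.consensus_subset(sols)
        assert len(subset) == 2

    def test_size_is_median_of_fold_sizes(self):
        sizes = [1, 3, 5]
        sols = []
        for k in sizes:
            s = _solution([90, 80, 70, 60, 50])
            s.final_subset = [f"f{j}" for j in range(k)]
            sols.append(s)
        subset, _ = ns.consensus_subset(sols)
        assert len(subset) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ns.consensus_subset([])


class TestEndToEndSelection:
    def test_planted_features_recovered(self):
        spec = ns.SyntheticPanelSpec(n_features=20, n_informative=4,
                                     effect_size=3.0, seed=2)
        matrix, labels = ns.generate_dmax_matrix(spec, effect_structure="complementary")
        subset, sols, imp = ns.run_feature_selection(
            matrix, labels, n_folds=3, seed=2, config=CFG,
            tune_every_iteration=False)
        planted = set(spec.feature_names[:4])
        # the top of the averaged importance ranking is dominated by planted features
        assert len(planted & set(imp.index[:6])) >= 3

    def test_selected_subset_beats_random_subset(self):
        """Paired comparison over seeds: accuracy of the selected subset is
        at least that of a random subset of equal size."""
        wins, ties, losses = 0, 0, 0
        for seed in range(5):
            spec = ns.SyntheticPanelSpec(n_features=15, n_informative=3,
                                         effect_size=3.0, seed=seed)
            matrix, labels = ns.generate_dmax_matrix(spec, effect_structure="shared")
            subset, _, _ = ns.run_feature_selection(
                matrix, labels, n_folds=3, seed=seed, config=CFG,
                tune_every_iteration=False)
            rng = np.random.default_rng(seed)
            random_subset = list(rng.choice(matrix.index, size=len(subset), replace=False))
            acc_sel = ns.nested_cv(matrix.loc[subset], labels, n_folds=3, n_trials=1,
                                   seed=seed, config=CFG).summary["mean_balanced_accuracy"]
            acc_rnd = ns.nested_cv(matrix.loc[random_subset], labels, n_folds=3, n_trials=1,
                                   seed=seed, config=CFG).summary["mean_balanced_accuracy"]
            if acc_sel > acc_rnd:
                wins += 1
            elif acc_sel == acc_rnd:
                ties += 1
            else:
                losses += 1
        assert wins >= losses
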