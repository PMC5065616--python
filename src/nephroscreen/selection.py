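"""Recursive feature elimination with automatic subset-size selection.

Starting from all features, the eliminator repeatedly trains a random forest
on the training compounds, ranks features by out-of-bag permutation
importance, drops the least important feature(s), and records the balanced
accuracy acc_j of each retained subset F_j on the independent RF-test
compounds.  Because small-sample accuracy trajectories are not smooth, the
final subset is not the argmax: the acc_j values are clustered with 1-D
Gaussian mixtures of 2-4 components, the component count is chosen by the
Bayesian information criterion BIC = -2*L_m + N_d*log(N_s) (N_d = 3K-1 for K
components in one dimension), and the smallest subset inside the
highest-mean-accuracy component is selected.  A spline/local-maximum variant
of the selector is provided as an explicit alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .classify import (CVPartition, RFConfig, _xy, grid_search, normalize,
                       oob_permutation_importance, performance_metrics,
                       train_random_forest, make_partitions)


@dataclass
class TrajectoryPoint:
    features: tuple[str, ...]
    accuracy: float
    importances: pd.Series  # importance per retained feature at this step


@dataclass
class RFESolution:
    """Elimination trajectory plus the selected final subset."""

    trajectory: list[TrajectoryPoint]
    final_subset: list[str]
    gmm: "GMMSelection | None" = None

    @property
    def sizes(self) -> list[int]:
        return [len(p.features) for p in self.trajectory]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([p.accuracy for p in self.trajectory])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.sizes, "accuracy": self.accuracies})


@dataclass
class GMMSelection:
    """Fitted mixture candidates and the BIC-chosen grouping."""

    candidates: dict[int, dict]  # k -> {means, weights, bic}
    chosen_k: int
    assignments: np.ndarray  # component index per trajectory point
    best_component: int


def rank_features(clf, X: np.ndarray, y: np.ndarray, feature_names: list[str],
                  seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance per feature, catalog-order stable."""
    imp = oob_permutation_importance(clf, X, y, seed=seed)
    return pd.Series(imp, index=feature_names)


def rfe(matrix: pd.DataFrame, labels: pd.Series, partition: CVPartition,
        config: RFConfig | None = None, seed: int = 0,
        step: int | float = 1, tune_every_iteration: bool = True) -> RFESolution:
    """Run the elimination loop over one four-set partition.

    ``matrix`` is a normalized features x compounds matrix.  An integer
    ``step`` drops that many features per iteration (1 by default, i.e. a
    full dense trajectory down to a single feature); a float in (0, 1) is a
    geometric speed option that drops that fraction of the retained set per
    iteration while more than 10 features remain, then proceeds 1-by-1, so
    the small-subset region where selection happens stays densely sampled.
    Tuning of (N_tree, N_trial) on (training, FS-test) is repeated each
    iteration unless ``tune_every_iteration=False``, in which case the
    parameters tuned on the full feature set are reused — a documented speed
    option.  Ranking uses the training compounds only; acc_j is measured on
    the RF-test compounds.  The returned solution has no final subset chosen
    yet (see :func:`gmm_select` / :func:`spline_select`).
    """
    config = config or RFConfig()
    partition.validate(matrix.columns)
    rng = np.random.default_rng(seed)
    features = list(matrix.index)
    trajectory: list[TrajectoryPoint] = []
    params = None
    while features:
        sub = matrix.loc[features]
        X_tr, y_tr = _xy(sub, labels, partition.training)
        X_fs, y_fs = _xy(sub, labels, partition.fs_test)
        X_rf, y_rf = _xy(sub, labels, partition.rf_test)
        it_seed = int(rng.integers(0, 2**31))
        if params is None or tune_every_iteration:
            params = grid_search(X_tr, y_tr, X_fs, y_fs, config, it_seed)
        clf = train_random_forest(X_tr, y_tr, params[0], params[1], it_seed)
        importances = rank_features(clf, X_tr, y_tr, features, seed=it_seed)
        acc = performance_metrics(y_rf, clf.predict(X_rf))["balanced_accuracy"]
        trajectory.append(TrajectoryPoint(features=tuple(features), accuracy=acc,
                                          importances=importances))
        if len(features) == 1:
            break
        # stable sort keeps catalog order among ties; drop the least important
        if isinstance(step, float):
            if not 0.0 < step < 1.0:
                raise ValueError("fractional step must lie in (0, 1)")
            n_drop = max(1, int(round(step * len(features)))) if len(features) > 10 else 1
        else:
            n_drop = int(step)
        order = importances.to_numpy().argsort(kind="stable")
        drop = {features[i] for i in order[: min(n_drop, len(features) - 1)]}
        features = [f for f in features if f not in drop]
    return RFESolution(trajectory=trajectory, final_subset=list(trajectory[-1].features))


def gmm_select(solution: RFESolution, max_components: int = 4, seed: int = 0,
               ) -> list[str]:
    """Choose the final subset by 1-D Gaussian-mixture clustering of acc_j.

    Mixtures with 2..4 components (capped by the number of distinct
    trajectory points) are fitted by EM with k-means initialization and 10
    restarts; the component count minimizes BIC; within the component of
    highest mean accuracy the smallest feature subset is returned.  A
    degenerate trajectory (all acc_j equal) yields the single-feature subset.
    """
    acc = solution.accuracies
    if len(acc) < 4:
        raise ValueError("need a trajectory of at least 4 points to cluster")
    sizes = np.array(solution.sizes)
    if np.ptp(acc) < 1e-9:
        chosen = solution.trajectory[int(np.argmin(sizes))]
        solution.final_subset = list(chosen.features)
        return solution.final_subset

    X = acc.reshape(-1, 1)
    candidates: dict[int, dict] = {}
    best_k, best_bic, best_model = None, np.inf, None
    for k in range(2, max_components + 1):
        if k > len(np.unique(acc)):
            continue
        gm = GaussianMixture(n_components=k, n_init=10, init_params="kmeans",
                             random_state=seed % (2**31))
        gm.fit(X)
        bic = float(gm.bic(X))
        candidates[k] = {"means": gm.means_.ravel().tolist(),
                         "weights": gm.weights_.tolist(), "bic": bic}
        if bic < best_bic:
            best_k, best_bic, best_model = k, bic, gm
    assign = best_model.predict(X)
    best_component = int(np.argmax(best_model.means_.ravel()))
    in_group = np.where(assign == best_component)[0]
    chosen_idx = in_group[np.argmin(sizes[in_group])]
    solution.gmm = GMMSelection(candidates=candidates, chosen_k=best_k,
                                assignments=assign, best_component=best_component)
    solution.final_subset = list(solution.trajectory[int(chosen_idx)].features)
    return solution.final_subset


def spline_select(solution: RFESolution, percentile: float = 5.0) -> list[str]:
    """Alternative selector: spline smoothing plus a Gaussian tolerance band.

    A cubic smoothing spline is fitted to acc_j versus subset size; the local
    maximum with the smallest number of features anchors a Gaussian band
    whose half-width is the ``percentile`` two-sided tail of the residual
    spread, and the smallest subset whose accuracy falls inside the band is
    selected.
    """
    from scipy.interpolate import UnivariateSpline
    from scipy.stats import norm

    sizes = np.array(solution.sizes, dtype=float)
    acc = solution.accuracies
    order = np.argsort(sizes)
    xs, ys = sizes[order], acc[order]
    if len(xs) < 4:
        raise ValueError("need at least 4 trajectory points")
    spl = UnivariateSpline(xs, ys, k=3, s=len(xs) * np.var(ys) * 0.1)
    smooth = spl(xs)
    # local maxima of the smoothed curve; anchor = the one at smallest size
    is_max = np.r_[False, (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] >= smooth[2:]), False]
    anchors = np.where(is_max)[0]
    anchor = anchors[0] if anchors.size else int(np.argmax(smooth))
    sigma = float(np.std(ys - smooth, ddof=0)) or 1e-12
    z = norm.ppf(1.0 - percentile / 100.0)
    lo, hi = smooth[anchor] - z * sigma, smooth[anchor] + z * sigma
    inside = np.where((ys >= lo) & (ys <= hi))[0]
    pick = inside[0] if inside.size else anchor  # xs sorted ascending: smallest size first
    chosen_size = xs[pick]
    idx = int(np.argmin(np.abs(np.array(solution.sizes) - chosen_size)))
    solution.final_subset = list(solution.trajectory[idx].features)
    return solution.final_subset


def consensus_subset(solutions: list[RFESolution]) -> tuple[list[str], pd.Series]:
    """Cross-fold consensus subset F_s with average importance values.

    Features are ranked by their importance averaged over each fold's
    full-feature-set ranking; F_s is the top-k, with k the median selected
    subset size across folds (rounded to the nearest integer).
    """
    if not solutions:
        raise ValueError("need at least one fold solution")
    imp = pd.concat([s.trajectory[0].importances for s in solutions], axis=1)
    avg = imp.mean(axis=1).sort_values(ascending=False, kind="stable")
    k = int(np.rint(np.median([len(s.final_subset) for s in solutions])))
    k = max(k, 1)
    return list(avg.index[:k]), avg


def run_feature_selection(matrix: pd.DataFrame, labels: pd.Series,
                          n_folds: int = 10, seed: int = 0,
                          config: RFConfig | None = None, step: int = 1,
                          selector: str = "gmm",
                          tune_every_iteration: bool = True,
                          ) -> tuple[list[str], list[RFESolution], pd.Series]:
    """Per-fold RFE + subset selection and the cross-fold consensus F_s.

    Normalization and elimination are driven by training compounds within
    each fold; the held-out outer fold is never touched.  Returns
    ``(F_s, fold_solutions, average_importances)``.
    """
    labels = labels.loc[matrix.columns]
    rng = np.random.default_rng(seed)
    solutions = []
    for part in make_partitions(labels, n_folds, trial=0, seed=seed):
        coeff, _ = normalize(matrix[part.training])
        norm = coeff.apply(matrix)
        fold_seed = int(rng.integers(0, 2**31))
        sol = rfe(norm, labels, part, config=config, seed=fold_seed, step=step,
                  tune_every_iteration=tune_every_iteration)
        if selector == "gmm":
            gmm_select(sol, seed=fold_seed)
        elif selector == "spline":
            spline_select(sol)
        else:
            raise ValueError("selector must be 'gmm' or 'spline'")
        solutions.append(sol)
    subset, avg_importance = consensus_subset(solutions)
    return subset, solutions, avg_importance
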