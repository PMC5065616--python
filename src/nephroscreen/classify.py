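"""Binary PTC-toxicity classification from Dmax feature matrices.

The estimator of generalization performance is a four-set nested stratified
10-fold cross-validation: each outer fold holds out a test set of compounds
(X_test) that never touches normalization, parameter tuning, or feature
selection; the remaining compounds are split (stratified, 60/20/20) into
X_training, X_FStest (grid search of the random-forest parameters N_tree and
N_trial) and X_RFtest (feature-subset evaluation during recursive feature
elimination).  The whole procedure is repeated over independent trials with
different random fold divisions and results are averaged over every fold and
trial.  The unit of splitting is the compound, so training and test samples
always come from different compounds.

Performance is reported as sensitivity, specificity (percent) and their mean,
the balanced accuracy, whose chance level is 50 %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "PTC-toxic"
NEGATIVE_LABEL = "non-PTC-toxic"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationCoefficients:
    """Per-feature min/max estimated on training data only.

    The map is f <- 2*(f - f_min)/(f_max - f_min) - 1, sending the training
    minimum to -1 and maximum to +1; test values may land outside [-1, 1].
    Constant training features map to 0.
    """

    f_min: pd.Series
    f_max: pd.Series

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        span = self.f_max - self.f_min
        constant = span == 0
        safe_span = span.replace(0, 1.0)
        out = 2.0 * matrix.sub(self.f_min, axis=0).div(safe_span, axis=0) - 1.0
        if constant.any():
            out.loc[constant.index[constant]] = 0.0
        return out

    def invert(self, matrix: pd.DataFrame) -> pd.DataFrame:
        span = (self.f_max - self.f_min).replace(0, 1.0)
        return (matrix + 1.0) / 2.0 * span.values[:, None] + self.f_min.values[:, None]


def normalize(train_matrix: pd.DataFrame) -> tuple[NormalizationCoefficients, pd.DataFrame]:
    """Estimate [-1, 1] normalization on a features x compounds training matrix."""
    f_min = train_matrix.min(axis=1)
    f_max = train_matrix.max(axis=1)
    if (f_max == f_min).any():
        bad = f_min.index[f_max == f_min].tolist()
        logger.warning("constant training features mapped to 0: %s", bad)
    coeff = NormalizationCoefficients(f_min=f_min, f_max=f_max)
    return coeff, coeff.apply(train_matrix)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    """Grid-search space for the forest size and per-split feature draw."""

    n_tree_grid: tuple[int, ...] = (10, 50, 150, 250, 400, 500)
    n_trial_grid: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        for grid in (self.n_tree_grid, self.n_trial_grid):
            if not grid or any(int(g) <= 0 for g in grid):
                raise ValueError("parameter grids must be nonempty positive integers")


def train_random_forest(X: np.ndarray, y: np.ndarray, n_tree: int, n_trial: int,
                        seed: int) -> RandomForestClassifier:
    """Bagged ensemble of ``n_tree`` trees with ``n_trial`` candidate features
    per split and majority-vote prediction."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=int(n_tree),
        max_features=min(int(n_trial), X.shape[1]),
        bootstrap=True,
        random_state=int(seed) % (2**31),
    )
    clf.fit(X, y)
    return clf


def oob_permutation_importance(clf: RandomForestClassifier, X: np.ndarray,
                               y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Breiman-style permutation importance on the out-of-bag data.

    For each tree, the accuracy on its out-of-bag samples is compared with
    the accuracy after permuting one feature at a time; the importance of a
    feature is the mean accuracy drop over trees with out-of-bag samples.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_samples, n_features = X.shape
    drops = np.zeros(n_features)
    n_used = 0
    for tree, sample_idx in zip(clf.estimators_, clf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n_samples), sample_idx, assume_unique=False)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        # individual trees predict encoded class indices
        decode = clf.classes_
        baseline = np.mean(decode[tree.predict(X_oob).astype(int)] == y_oob)
        # one stacked prediction call covering all single-feature permutations
        stacked = np.repeat(X_oob[None, :, :], n_features, axis=0)
        for f in range(n_features):
            stacked[f, :, f] = rng.permutation(X_oob[:, f])
        preds = decode[tree.predict(stacked.reshape(-1, n_features)).astype(int)]
        permuted_acc = (preds.reshape(n_features, -1) == y_oob[None, :]).mean(axis=1)
        drops += baseline - permuted_acc
        n_used += 1
    if n_used == 0:
        raise ValueError("no tree had out-of-bag samples; dataset too small")
    return drops / n_used


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def performance_metrics(y_true, y_pred) -> dict[str, float]:
    """Confusion counts plus sensitivity/specificity/balanced accuracy in %."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL)))
    fn = int(np.sum((y_true == POSITIVE_LABEL) & (y_pred != POSITIVE_LABEL)))
    tn = int(np.sum((y_true != POSITIVE_LABEL) & (y_pred != POSITIVE_LABEL)))
    fp = int(np.sum((y_true != POSITIVE_LABEL) & (y_pred == POSITIVE_LABEL)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
    acc = (sens + spec) / 2.0
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "sensitivity": sens, "specificity": spec, "balanced_accuracy": acc}


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass
class CVPartition:
    """The four disjoint compound sets of one outer fold."""

    training: list[str]
    fs_test: list[str]
    rf_test: list[str]
    test: list[str]
    fold: int
    trial: int

    def validate(self, all_compounds) -> None:
        sets = [set(self.training), set(self.fs_test), set(self.rf_test), set(self.test)]
        union: set[str] = set()
        for s in sets:
            if union & s:
                raise ValueError(f"compound(s) {sorted(union & s)} appear in two partition sets")
            union |= s
        if union != set(all_compounds):
            raise ValueError("partition sets must cover all compounds exactly once")


def _stratified_split(compounds: np.ndarray, labels: np.ndarray, sizes: tuple[float, float, float],
                      seed: int) -> tuple[list[str], list[str], list[str]]:
    """Split compounds into three stratified groups with the given proportions."""
    rest_frac = sizes[1] + sizes[2]
    label_of = dict(zip(compounds, labels))
    training, rest = train_test_split(compounds, test_size=rest_frac,
                                      stratify=labels, random_state=seed % (2**31))
    rest_labels = np.array([label_of[c] for c in rest])
    fs_test, rf_test = train_test_split(rest, test_size=sizes[2] / rest_frac,
                                        stratify=rest_labels,
                                        random_state=(seed + 1) % (2**31))
    return list(training), list(fs_test), list(rf_test)


def make_partitions(labels: pd.Series, n_folds: int, trial: int, seed: int,
                    inner_sizes: tuple[float, float, float] = (0.6, 0.2, 0.2),
                    ) -> list[CVPartition]:
    """Outer stratified k-fold plus inner stratified 60/20/20 split.

    Stratification can degrade for classes smaller than ``n_folds``; sklearn
    emits a warning and assigns folds as evenly as possible in that case.
    """
    compounds = labels.index.to_numpy()
    y = labels.to_numpy()
    min_class = pd.Series(y).value_counts().min()
    if min_class < n_folds:
        logger.warning("smallest class has %d members < %d folds; using %d folds",
                       min_class, n_folds, min_class)
        n_folds = int(min_class)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=(seed + 104729 * trial) % (2**31))
    partitions = []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(compounds, y)):
        rest, rest_y = compounds[rest_idx], y[rest_idx]
        training, fs_test, rf_test = _stratified_split(
            rest, rest_y, inner_sizes, seed=seed + 13 * trial + fold)
        part = CVPartition(training=training, fs_test=fs_test, rf_test=rf_test,
                           test=list(compounds[test_idx]), fold=fold, trial=trial)
        part.validate(compounds)
        partitions.append(part)
    return partitions


# ---------------------------------------------------------------------------
# grid search and nested cross-validation
# ---------------------------------------------------------------------------

def _xy(matrix: pd.DataFrame, labels: pd.Series, compounds: list[str]):
    X = matrix[compounds].to_numpy().T
    y = labels.loc[compounds].to_numpy()
    return X, y


def grid_search(X_train, y_train, X_fs, y_fs, config: RFConfig, seed: int,
                ) -> tuple[int, int]:
    """Exhaustive search of the (N_tree, N_trial) grid by balanced accuracy
    on the feature-selection test set; ties break toward the smaller model."""
    best = (min(config.n_tree_grid), min(config.n_trial_grid))
    best_acc = -np.inf
    for n_tree in sorted(config.n_tree_grid):
        for n_trial in sorted(config.n_trial_grid):
            clf = train_random_forest(X_train, y_train, n_tree, n_trial, seed)
            acc = performance_metrics(y_fs, clf.predict(X_fs))["balanced_accuracy"]
            if np.isfinite(acc) and acc > best_acc:
                best_acc = acc
                best = (n_tree, n_trial)
    return best


@dataclass
class PerformanceReport:
    """Fold x trial metrics with aggregate summaries."""

    folds: pd.DataFrame  # one row per fold x trial
    per_compound: pd.Series  # fraction of times each compound was classified correctly
    selected_features: list[list[str]] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, float]:
        cols = ["sensitivity", "specificity", "balanced_accuracy", "training_accuracy"]
        out = {}
        for c in cols:
            if c in self.folds:
                vals = self.folds[c].dropna()
                out[f"mean_{c}"] = float(vals.mean())
                out[f"sem_{c}"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return out


def nested_cv(matrix: pd.DataFrame, labels: pd.Series, n_folds: int = 10,
              n_trials: int = 10, seed: int = 0, config: RFConfig | None = None,
              feature_selector=None, inner_sizes=(0.6, 0.2, 0.2),
              ) -> PerformanceReport:
    """Four-set nested stratified cross-validation of a Dmax matrix.

    ``matrix`` is features x compounds, ``labels`` a compound-indexed Series
    of class labels.  Normalization coefficients and classifier parameters
    are estimated on the training compounds only.  ``feature_selector``, if
    given, is called per fold as
    ``selector(norm_matrix, labels, partition, params, seed)`` and must
    return the list of retained feature names; by default all features are
    used.
    """
    config = config or RFConfig()
    labels = labels.loc[matrix.columns]
    rng = np.random.default_rng(seed)
    rows = []
    correct: dict[str, list[bool]] = {c: [] for c in matrix.columns}
    chosen_subsets: list[list[str]] = []

    for trial in range(n_trials):
        for part in make_partitions(labels, n_folds, trial, seed):
            fold_seed = int(rng.integers(0, 2**31))
            coeff, _ = normalize(matrix[part.training])
            norm = coeff.apply(matrix)

            X_tr, y_tr = _xy(norm, labels, part.training)
            X_fs, y_fs = _xy(norm, labels, part.fs_test)
            n_tree, n_trial_best = grid_search(X_tr, y_tr, X_fs, y_fs, config, fold_seed)

            features = list(matrix.index)
            if feature_selector is not None:
                features = feature_selector(norm, labels, part,
                                            (n_tree, n_trial_best), fold_seed)
                chosen_subsets.append(list(features))
            # the final fold classifier is refitted on all inner compounds
            # (training + FS-test + RF-test); the held-out X_test stays unseen
            sub = norm.loc[features]
            inner = part.training + part.fs_test + part.rf_test
            X_tr, y_tr = _xy(sub, labels, inner)
            X_te, y_te = _xy(sub, labels, part.test)
            clf = train_random_forest(X_tr, y_tr, n_tree, n_trial_best, fold_seed)
            metrics = performance_metrics(y_te, clf.predict(X_te))
            metrics["training_accuracy"] = performance_metrics(
                y_tr, clf.predict(X_tr))["balanced_accuracy"]
            metrics.update({"trial": trial, "fold": part.fold,
                            "n_tree": n_tree, "n_trial": n_trial_best,
                            "seed": fold_seed})
            rows.append(metrics)
            preds = clf.predict(X_te)
            for compound, ok in zip(part.test, preds == y_te):
                correct[compound].append(bool(ok))

    folds = pd.DataFrame(rows)
    per_compound = pd.Series({c: float(np.mean(v)) if v else np.nan
                              for c, v in correct.items()}, name="accuracy")
    return PerformanceReport(folds=folds, per_compound=per_compound,
                             selected_features=chosen_subsets)


def single_feature_screen(matrix: pd.DataFrame, labels: pd.Series,
                          catalog: pd.DataFrame | None = None,
                          n_folds: int = 10, n_trials: int = 10, seed: int = 0,
                          config: RFConfig | None = None) -> pd.DataFrame:
    """Nested-CV balanced accuracy of every single feature.

    Returns one row per feature with its mean balanced accuracy and, when a
    catalog is supplied, the marker and feature-type group, so group maxima
    (best feature per marker or per type) can be read off directly.
    """
    rows = []
    for k, feature in enumerate(matrix.index):
        report = nested_cv(matrix.loc[[feature]], labels, n_folds=n_folds,
                           n_trials=n_trials, seed=seed + k, config=config)
        s = report.summary
        rows.append({"feature": feature,
                     "balanced_accuracy": s["mean_balanced_accuracy"],
                     "sem": s["sem_balanced_accuracy"],
                     "training_accuracy": s.get("mean_training_accuracy", np.nan)})
    out = pd.DataFrame(rows).set_index("feature")
    if catalog is not None:
        meta = catalog.set_index("name")[["marker", "group"]]
        out = out.join(meta, how="left")
    return out


def group_maxima(screen: pd.DataFrame, by: str = "marker") -> pd.DataFrame:
    """Best single feature per marker or per feature-type group."""
    if by not in screen.columns:
        raise ValueError(f"screen table has no {by!r} column; pass a catalog to the screen")
    idx = screen.groupby(by)["balanced_accuracy"].idxmax()
    return screen.loc[idx].sort_values("balanced_accuracy", ascending=False)
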