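"""Descriptive analyses: clustering enrichment, correlations, MDS, cell scoring.

These are the exploratory companions of the classifier: two-way hierarchical
clustering of the Dmax matrix with hypergeometric enrichment of toxicity
classes in the compound clusters, feature-pair correlation across compounds
with one-sided group comparisons, classical (Torgerson) multidimensional
scaling in chemical (Tanimoto) or phenotypic (Euclidean) space, and
percent-positive scoring of single-cell marker distributions against vehicle
controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, pearsonr, ttest_ind

from .classify import POSITIVE_LABEL


@dataclass
class ClusterEnrichment:
    linkage_matrix: np.ndarray
    assignments: pd.Series  # cluster id (1, 2) per compound
    composition: pd.DataFrame  # percentage of each class per cluster
    p_values: pd.Series  # hypergeometric upper-tail P of majority-class enrichment


def hypergeom_upper_tail(n_hits: int, cluster_size: int, n_positive: int,
                         n_total: int) -> float:
    """P(X >= n_hits) for X ~ Hypergeometric(n_total, n_positive, cluster_size)."""
    return float(hypergeom.sf(n_hits - 1, n_total, n_positive, cluster_size))


def cluster_and_test(matrix: pd.DataFrame, labels: pd.Series, n_clusters: int = 2,
                     method: str = "average", metric: str = "euclidean",
                     ) -> ClusterEnrichment:
    """Agglomerative clustering of compounds plus class-enrichment tests.

    Compounds (matrix columns) are clustered on their Dmax profiles; the cut
    into ``n_clusters`` clusters is tested for enrichment of each cluster's
    majority class with an upper-tail hypergeometric test.  Transpose the
    matrix to cluster features instead.
    """
    labels = labels.loc[matrix.columns]
    Z = linkage(matrix.to_numpy().T, method=method, metric=metric)
    assign = pd.Series(fcluster(Z, t=n_clusters, criterion="maxclust"),
                       index=matrix.columns, name="cluster")
    if assign.value_counts().min() == 1:
        import logging
        logging.getLogger(__name__).warning("clustering cut produced a singleton cluster")

    n_total = len(labels)
    comp_rows = {}
    p_values = {}
    for cluster_id, members in assign.groupby(assign):
        in_cluster = labels.loc[members.index]
        counts = in_cluster.value_counts()
        comp_rows[cluster_id] = 100.0 * counts / len(in_cluster)
        majority = counts.idxmax()
        n_hits = int(counts.max())
        n_positive = int((labels == majority).sum())
        p_values[cluster_id] = hypergeom_upper_tail(n_hits, len(in_cluster),
                                                    n_positive, n_total)
    composition = pd.DataFrame(comp_rows).T.fillna(0.0)
    return ClusterEnrichment(linkage_matrix=Z, assignments=assign,
                             composition=composition,
                             p_values=pd.Series(p_values, name="P"))


def feature_pair_correlation(matrix: pd.DataFrame, feature_a: str, feature_b: str,
                             labels: pd.Series) -> dict[str, float]:
    """Correlation of two Dmax features across compounds and group contrasts.

    Returns Pearson r between the two features, the toxic-minus-nontoxic mean
    difference per feature, and one-sided two-sample t-test P values
    (alternative: toxic > non-toxic).  Zero-variance features give NaN r.
    """
    labels = labels.loc[matrix.columns]
    a = matrix.loc[feature_a].to_numpy(dtype=float)
    b = matrix.loc[feature_b].to_numpy(dtype=float)
    toxic = labels.to_numpy() == POSITIVE_LABEL
    out: dict[str, float] = {}
    if np.std(a) == 0 or np.std(b) == 0:
        out["r"] = np.nan
        out["r_p"] = np.nan
    else:
        r, p = pearsonr(a, b)
        out["r"] = float(r)
        out["r_p"] = float(p)
    for name, values in (("a", a), ("b", b)):
        out[f"delta_mu_{name}"] = float(values[toxic].mean() - values[~toxic].mean())
        t = ttest_ind(values[toxic], values[~toxic], alternative="greater")
        out[f"t_p_{name}"] = float(t.pvalue)
    return out


@dataclass
class MDSEmbedding:
    coordinates: pd.DataFrame  # columns MDS1, MDS2
    eigenvalues: np.ndarray


def classical_mds(dissimilarity: pd.DataFrame | np.ndarray, n_components: int = 2,
                  ) -> MDSEmbedding:
    """Torgerson scaling: double-center the squared dissimilarities, take the
    top eigenvectors scaled by the square roots of their eigenvalues."""
    if isinstance(dissimilarity, pd.DataFrame):
        index = dissimilarity.index
        D = dissimilarity.to_numpy(dtype=float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        index = pd.RangeIndex(len(D))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval[:n_components], 0.0, None)
    coords = eigvec[:, :n_components] * np.sqrt(pos)[None, :]
    frame = pd.DataFrame(coords, index=index,
                         columns=[f"MDS{i + 1}" for i in range(n_components)])
    return MDSEmbedding(coordinates=frame, eigenvalues=eigval)


def scale_features_01(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature (row) to [0, 1] by its observed min/max."""
    lo = matrix.min(axis=1)
    span = (matrix.max(axis=1) - lo).replace(0, 1.0)
    return matrix.sub(lo, axis=0).div(span, axis=0)


def phenotypic_dissimilarity(matrix: pd.DataFrame,
                             features: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Euclidean compound distances after [0, 1] feature scaling."""
    sub = matrix.loc[features] if features is not None else matrix
    X = scale_features_01(sub).to_numpy().T
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def tanimoto_dissimilarity(fingerprints: pd.DataFrame) -> pd.DataFrame:
    """1 - Tanimoto coefficient between binary fingerprints (rows = compounds).

    T = |A and B| / |A or B|, defined as 1 when both fingerprints are all
    zero (identical empty structures).
    """
    F = fingerprints.to_numpy()
    if not np.isin(F, (0, 1)).all():
        raise ValueError("fingerprints must be binary 0/1 vectors")
    F = F.astype(bool)
    inter = (F[:, None, :] & F[None, :, :]).sum(axis=2).astype(float)
    union = (F[:, None, :] | F[None, :, :]).sum(axis=2).astype(float)
    T = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return pd.DataFrame(1.0 - T, index=fingerprints.index, columns=fingerprints.index)


@dataclass
class PositiveCellScore:
    marker: str
    threshold: float
    percent_positive: float
    control_mean: float
    control_sd: float


def percent_positive(treated: np.ndarray, control: np.ndarray,
                     marker: str = "marker", sd_multiplier: float = 3.0,
                     min_control_cells: int = 50) -> PositiveCellScore:
    """Fraction of treated cells above a control-derived intensity threshold.

    The default policy places the threshold at the vehicle-control mean plus
    ``sd_multiplier`` control standard deviations; under a Gaussian control
    at +3 SD about 0.13 % of control-like cells score positive.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < min_control_cells:
        raise ValueError(
            f"need at least {min_control_cells} control cells, got {control.size}")
    mean = float(control.mean())
    sd = float(control.std(ddof=0))
    threshold = mean + sd_multiplier * sd
    percent = 100.0 * float(np.mean(treated > threshold))
    return PositiveCellScore(marker=marker, threshold=threshold,
                             percent_positive=percent, control_mean=mean,
                             control_sd=sd)


# ---------------------------------------------------------------------------
# plotting helpers
# ---------------------------------------------------------------------------

def plot_dmax_heatmap(matrix: pd.DataFrame, labels: pd.Series | None = None):
    """Clustered Dmax heatmap (features x compounds)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    row_order = leaves_list(linkage(matrix.to_numpy(), method="average"))
    col_order = leaves_list(linkage(matrix.to_numpy().T, method="average"))
    data = matrix.iloc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xlabel("compounds")
    ax.set_ylabel("features")
    fig.colorbar(im, ax=ax, label="Dmax (log2)")
    return fig


def plot_mds(embedding: MDSEmbedding, labels: pd.Series | None = None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    coords = embedding.coordinates
    if labels is not None:
        for value, group in coords.groupby(labels.loc[coords.index]):
            ax.scatter(group["MDS1"], group["MDS2"], label=str(value), s=30)
        ax.legend()
    else:
        ax.scatter(coords["MDS1"], coords["MDS2"], s=30)
    ax.set_xlabel("MDS1")
    ax.set_ylabel("MDS2")
    return fig


def plot_rfe_trajectory(solution) -> "object":
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(solution.sizes, solution.accuracies, "o-", ms=3)
    ax.axvline(len(solution.final_subset), color="red", ls="--",
               label=f"selected ({len(solution.final_subset)} features)")
    ax.set_xlabel("retained features")
    ax.set_ylabel("balanced accuracy (%)")
    ax.invert_xaxis()
    ax.legend()
    return fig
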