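"""Unsupervised assessment: PCA, hierarchical clustergram cuts, K-means.

Feature tables are reduced to leading principal-component scores ("top 10
features selected using PCA" read as component scores), then assessed
with (a) Ward/Euclidean agglomerative clustering cut at two clusters and
(b) seeded K-means on the top two components with the cluster count
chosen by an elbow (maximum discrete curvature of within-cluster sum of
squares).  Cluster composition is reported both ways: class percentages
within each cluster (summing to 100 per cluster) and the share of each
class captured by each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .types import REBOUNDER, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    method: str
    k: int
    assignments: pd.Series  # eye_id -> cluster id (0-based, ordered by rebounder share desc)
    composition: pd.DataFrame  # cluster x class, % of cluster members (rows sum to 100)
    class_capture: pd.DataFrame  # cluster x class, % of each class in the cluster
    metadata: dict = field(default_factory=dict)
    weak_elbow: bool = False


def pca_reduce(table: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Scores on the leading principal components (centered data).

    Component signs are fixed by making the largest-magnitude loading
    positive, so reduction is deterministic.
    """
    n, p = table.shape
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}"
        )
    X = table.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, 0.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=table.index, columns=[f"PC{j + 1}" for j in range(n_components)]
    )


def _report(
    method: str,
    assign: np.ndarray,
    index: pd.Index,
    labels: pd.Series,
    metadata: dict,
) -> ClusterReport:
    labels = labels.reindex(index)
    classes = sorted(labels.unique(), key=lambda c: (c != REBOUNDER, c))
    clusters = np.unique(assign)
    # order clusters by rebounder share (descending) for reporting stability
    def reb_share(c: int) -> float:
        members = labels[assign == c]
        return -np.mean(members == REBOUNDER) if len(members) else 0.0

    order = sorted(clusters, key=lambda c: (reb_share(c), c))
    relabel = {old: new for new, old in enumerate(order)}
    assign = np.array([relabel[a] for a in assign])

    comp_rows, capture_rows = [], []
    for c in range(len(clusters)):
        members = labels[assign == c]
        comp_rows.append(
            {cls: 100.0 * np.mean(members == cls) if len(members) else 0.0 for cls in classes}
        )
        capture_rows.append(
            {cls: 100.0 * np.sum(members == cls) / max((labels == cls).sum(), 1) for cls in classes}
        )
    comp = pd.DataFrame(comp_rows, index=pd.RangeIndex(len(clusters), name="cluster"))
    capture = pd.DataFrame(capture_rows, index=pd.RangeIndex(len(clusters), name="cluster"))
    return ClusterReport(
        method=method,
        k=len(clusters),
        assignments=pd.Series(assign, index=index, name="cluster"),
        composition=comp,
        class_capture=capture,
        metadata=metadata,
    )


def hierarchical_cut(
    reduced: pd.DataFrame, labels: pd.Series, n_clusters: int = 2
) -> ClusterReport:
    """Ward/Euclidean agglomerative clustering cut at ``n_clusters``."""
    if len(reduced) < 2:
        raise ValidationError("need >= 2 rows to cluster")
    Z = linkage(reduced.to_numpy(dtype=float), method="ward", metric="euclidean")
    assign = fcluster(Z, t=min(n_clusters, len(reduced)), criterion="maxclust") - 1
    return _report(
        "hierarchical", assign, reduced.index, labels,
        {"linkage": "ward", "metric": "euclidean"},
    )


def _wcss_curve(X: np.ndarray, k_max: int, seed: int, n_restarts: int = 10) -> np.ndarray:
    wcss = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        wcss.append(km.inertia_)
    return np.asarray(wcss)


def elbow_k(reduced: pd.DataFrame, k_max: int = 6, seed: int = 0) -> tuple[int, bool]:
    """Elbow choice of k: maximum discrete curvature of the WCSS curve.

    Returns ``(k, weak_elbow)``; the elbow is flagged weak when the best
    curvature does not exceed twice the runner-up.
    """
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    n = len(reduced)
    if n < k_max:
        logger.warning("k_max lowered from %d to %d (only %d rows)", k_max, n, n)
        k_max = n
    X = reduced.to_numpy(dtype=float)
    wcss = _wcss_curve(X, k_max, seed)
    if k_max < 3:
        return k_max, True
    # discrete second difference of WCSS at k = 2..k_max-1
    curvature = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]
    ks = np.arange(2, k_max)
    best = int(np.argmax(curvature))
    k = int(ks[best])
    others = np.delete(curvature, best)
    weak = bool(
        curvature[best] <= 0
        or (others.size > 0 and others.max() > 0 and curvature[best] < 2 * others.max())
    )
    if weak:
        logger.info("weak elbow: curvature contrast < 2x (k=%d)", k)
    return k, weak


def kmeans_composition(
    reduced_2pc: pd.DataFrame, k: int, labels: pd.Series, seed: int = 0
) -> ClusterReport:
    """Seeded K-means (10 restarts, best inertia) on the top two PC scores."""
    if k > len(reduced_2pc):
        raise ValidationError(f"k={k} exceeds {len(reduced_2pc)} rows")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(reduced_2pc.to_numpy(dtype=float))
    return _report(
        "kmeans", assign, reduced_2pc.index, labels,
        {"n_init": 10, "seed": seed, "inertia": float(km.inertia_)},
    )


def plot_clustergram(
    reduced: pd.DataFrame, labels: pd.Series, path=None
):
    """Dendrogram + heatmap of the reduced table (rows reordered by linkage)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    Z = linkage(reduced.to_numpy(dtype=float), method="ward")
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(9, 5), gridspec_kw={"width_ratios": [1, 3]}
    )
    dd = dendrogram(Z, orientation="left", no_labels=True, ax=ax_d)
    order = dd["leaves"]
    data = reduced.to_numpy(dtype=float)[order]
    ax_h.imshow(data, aspect="auto", cmap="viridis")
    ax_h.set_yticks(range(len(order)))
    ax_h.set_yticklabels(
        [f"{reduced.index[i]} ({labels.reindex(reduced.index).iloc[i]})" for i in order],
        fontsize=5,
    )
    ax_h.set_xticks(range(reduced.shape[1]))
    ax_h.set_xticklabels(reduced.columns, rotation=90, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
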