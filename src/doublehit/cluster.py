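"""Unsupervised class discovery on methylation profiles.

Agglomerative hierarchical clustering of samples with the number of
clusters chosen by minimizing the Davies-Bouldin index over a candidate
range, PCA on the significant-probe submatrix, and a Fisher-exact test for
association between cluster membership and diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

logger = logging.getLogger("doublehit")

__all__ = [
    "ClusteringResult",
    "PcaResult",
    "hierarchical_cluster",
    "davies_bouldin",
    "select_k_and_label",
    "cluster_separation_test",
    "pca",
]


def hierarchical_cluster(
    m: np.ndarray | pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> np.ndarray:
    """Agglomerative linkage over rows (samples); SciPy merge-table format."""
    X = np.asarray(m, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >=2 samples to cluster")
    if np.isnan(X).any():
        raise ValueError("NaNs in clustering input")
    return linkage(X, method=method, metric=metric)


def davies_bouldin(m: np.ndarray | pd.DataFrame, labels) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (S_i + S_j) / d(c_i, c_j) ratio, with S_i the mean Euclidean distance of
    members to their centroid. Lower is better; 0 for perfectly tight
    clusters. Coincident centroids make the ratio undefined -> error.
    """
    X = np.asarray(m, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >=2 clusters")
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    k = len(uniq)
    db = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0:
                raise ValueError(f"coincident centroids for clusters {uniq[i]} and {uniq[j]}")
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        db += worst
    return db / k


@dataclass
class ClusteringResult:
    linkage_tree: np.ndarray
    k_candidates: list[int]
    db_index_by_k: dict[int, float]
    k_star: int
    labels: pd.Series  # sample id -> cluster id (1..k_star)
    separation_p: float | None = None
    flat_db_curve: bool = field(default=False)


def select_k_and_label(
    tree: np.ndarray, m: np.ndarray | pd.DataFrame, k_range=range(2, 6)
) -> ClusteringResult:
    """Cut the tree at each candidate k and keep the Davies-Bouldin minimizer.

    Ties break toward the smaller k. A DB curve flat within 1% of its range
    is flagged (no real structure; k_star still reported).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    X = np.asarray(m, dtype=float)
    index = m.index if isinstance(m, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    db_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(k_range):
        lab = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue  # cut produced a single cluster; DB undefined
        try:
            db_by_k[k] = davies_bouldin(X, lab)
        except ValueError:
            continue
        labels_by_k[k] = lab
    if not db_by_k:
        raise ValueError("no candidate k produced >=2 distinct, separable clusters")
    k_star = min(db_by_k, key=lambda k: (db_by_k[k], k))
    vals = np.array(list(db_by_k.values()))
    flat = bool(np.ptp(vals) <= 0.01 * max(np.abs(vals).max(), 1e-12))
    if flat:
        logger.warning("select_k_and_label: DB curve flat within 1%%; structure doubtful (k_star=%d)", k_star)
    return ClusteringResult(
        linkage_tree=tree,
        k_candidates=sorted(db_by_k),
        db_index_by_k=db_by_k,
        k_star=k_star,
        labels=pd.Series(labels_by_k[k_star], index=index, name="cluster"),
        flat_db_curve=flat,
    )


def cluster_separation_test(labels, diagnosis, target: str | None = None) -> float:
    """Fisher exact test for cluster/diagnosis association (two-sided).

    The cluster most enriched for the target diagnosis is collapsed
    one-vs-rest against target-vs-other diagnosis, giving a 2x2 table.
    Degenerate tables (a label or diagnosis with no counterpart) return
    p=1 with a warning.
    """
    labels = pd.Series(np.asarray(labels))
    diagnosis = pd.Series(np.asarray(diagnosis))
    if len(labels) != len(diagnosis):
        raise ValueError("labels and diagnosis must cover the same samples")
    if target is None:
        target = diagnosis.value_counts().idxmin()  # rarest diagnosis by default
    is_target = (diagnosis == target).to_numpy()
    if labels.nunique() < 2 or is_target.all() or not is_target.any():
        logger.warning("cluster_separation_test: degenerate table, returning p=1")
        return 1.0
    # cluster with highest target fraction
    frac = pd.Series(is_target).groupby(labels.to_numpy()).mean()
    best = frac.idxmax()
    in_best = (labels == best).to_numpy()
    table = [
        [int((in_best & is_target).sum()), int((in_best & ~is_target).sum())],
        [int((~in_best & is_target).sum()), int((~in_best & ~is_target).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class PcaResult:
    component_scores: pd.DataFrame      # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame              # features x components


def pca(m: np.ndarray | pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Centered PCA (SVD); scores, variance ratios, loadings."""
    X = np.asarray(m, dtype=float)
    n_components = min(n_components, min(X.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    sample_index = m.index if isinstance(m, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    feat_index = m.columns if isinstance(m, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        component_scores=pd.DataFrame(scores, index=sample_index, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=pd.DataFrame(model.components_.T, index=feat_index, columns=cols),
    )
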