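"""Unsupervised sample grouping, heatmap ordering and per-feature group tests.

Grouping is K-means on z-scored features (so high-abundance genera do not
dominate the Euclidean geometry), with silhouette-based selection of the
number of clusters when ``k="auto"``.  Group comparisons default to Welch's
t-test with Benjamini-Hochberg adjustment across the feature batch.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, to_relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "GroupAssignment",
    "GroupTestResult",
    "KMeansGrouper",
    "kmeans_groups",
    "heatmap_matrix",
    "compare_groups",
]


@dataclasses.dataclass
class GroupAssignment:
    labels: dict[str, int]  # sample id -> cluster label in 0..k-1
    k: int
    inertia: float
    silhouette_by_k: dict[int, float]
    seed: int | None


@dataclasses.dataclass
class GroupTestResult:
    feature: str
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    p_adjusted: float
    direction: str  # "A>B" or "B>A"
    test: str


class KMeansGrouper(BaseEstimator, ClusterMixin):
    """K-means sample grouping with internal feature standardization.

    Lloyd's algorithm with k-means++ initialization and ``n_init`` restarts;
    ``n_clusters="auto"`` scans k = 2..max_k and keeps the k with the highest
    mean silhouette (Euclidean).

    Parameters
    ----------
    n_clusters : int or "auto", default=2
    n_init : int, default=25
        Random restarts; the best-inertia solution is kept.
    max_k : int, default=8
        Upper end of the "auto" scan.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
    k_ : int
        Chosen number of clusters.
    inertia_ : float
    silhouette_by_k_ : dict
        Mean silhouette per scanned k (single entry when k was fixed).
    """

    def __init__(self, n_clusters=2, n_init=25, max_k=8, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_k = max_k
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x variables")
        if np.all(X.std(axis=0) == 0):
            raise ValueError("constant feature matrix cannot be clustered")
        Z = StandardScaler().fit_transform(X)
        Z = Z[:, np.isfinite(Z).all(axis=0)]  # drop constant columns

        if self.n_clusters == "auto":
            ks = range(2, min(self.max_k, X.shape[0] - 1) + 1)
        else:
            k = int(self.n_clusters)
            if k < 1 or k > X.shape[0]:
                raise ValueError(f"invalid n_clusters {k} for {X.shape[0]} samples")
            ks = [k]

        self.silhouette_by_k_ = {}
        best = None
        for k in ks:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=self.n_init,
                random_state=self.random_state,
            ).fit(Z)
            if 1 < k < X.shape[0]:
                sil = float(silhouette_score(Z, km.labels_))
            else:
                sil = float("nan")
            self.silhouette_by_k_[k] = sil
            if best is None or (
                self.n_clusters == "auto" and sil > self.silhouette_by_k_[best[0]]
            ):
                best = (k, km)
        self.k_, km = best
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_groups(
    features: pd.DataFrame, k=2, seed: int | None = None, n_init: int = 25
) -> GroupAssignment:
    """Cluster samples (rows of ``features``) into k groups."""
    grouper = KMeansGrouper(n_clusters=k, n_init=n_init, random_state=seed)
    grouper.fit(features.to_numpy())
    return GroupAssignment(
        labels={str(s): int(l) for s, l in zip(features.index, grouper.labels_)},
        k=grouper.k_,
        inertia=grouper.inertia_,
        silhouette_by_k=grouper.silhouette_by_k_,
        seed=seed,
    )


def heatmap_matrix(
    table: AbundanceTable, groups: GroupAssignment | None = None
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-z-scored matrix with taxa and samples ordered by average-linkage
    hierarchical clustering (Bray-Curtis over samples, correlation distance
    over taxa).  Returns (ordered z-matrix, taxa order, sample order)."""
    if table.n_taxa < 2 or table.n_samples < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    rel = to_relative_abundance(table).values

    sample_d = pdist(rel.T, metric="braycurtis")
    sample_order = leaves_list(linkage(sample_d, method="average"))

    mu = rel.mean(axis=1, keepdims=True)
    sd = rel.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (rel - mu) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        taxa_d = pdist(z, metric="correlation")
    taxa_d = np.nan_to_num(taxa_d, nan=1.0)
    taxa_order = leaves_list(linkage(taxa_d, method="average"))

    taxa_ids = [table.taxa_ids[i] for i in taxa_order]
    sample_ids = [table.sample_ids[j] for j in sample_order]
    ordered = pd.DataFrame(
        z[np.ix_(taxa_order, sample_order)], index=taxa_ids, columns=sample_ids
    )
    return ordered, taxa_ids, sample_ids


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        logger.info("zero variance in a group; falling back to Mann-Whitney")
        return _mannwhitney(a, b)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p), "welch"


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    # Exact null distribution for small groups, normal approximation with tie
    # correction once either group exceeds 8 samples.
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p), "mannwhitney"


def compare_groups(
    values: pd.DataFrame,
    groups: pd.Series,
    method: str = "welch",
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Two-group tests per feature with BH adjustment across the batch.

    ``values`` is samples x features; ``groups`` maps the same samples to two
    labels (the first label in sorted order is reported as "A").
    """
    groups = groups.loc[values.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    mask_a = (groups == labels[0]).to_numpy()
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("need at least 2 samples per group")

    results = []
    for feat in values.columns:
        x = values[feat].to_numpy(dtype=float)
        a, b = x[mask_a], x[~mask_a]
        if method == "welch":
            stat, p, used = _welch(a, b)
        elif method == "mannwhitney":
            stat, p, used = _mannwhitney(a, b)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(
            GroupTestResult(
                feature=str(feat),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                statistic=stat,
                p_value=p,
                p_adjusted=np.nan,
                direction="A>B" if a.mean() >= b.mean() else "B>A",
                test=used,
            )
        )
    _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results
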