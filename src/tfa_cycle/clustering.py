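"""Hierarchical clustering of activity profiles on absolute values.

Factors acting as activators versus repressors of the same program show
mirror-image activity curves, so profiles are clustered on |alpha|: a
profile and its negation are at distance zero and always co-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core_io import ActivityMatrix, DataValidationError


@dataclass
class ClusteringResult:
    tf_ids: tuple[str, ...]
    linkage_matrix: np.ndarray
    labels: np.ndarray
    n_clusters: int
    metric: str
    method: str

    def members(self, label: int) -> list[str]:
        return [tf for tf, l in zip(self.tf_ids, self.labels) if l == label]


def cluster_profiles(activity: ActivityMatrix, n_clusters: int = 2,
                     metric: str = "euclidean",
                     method: str = "average") -> ClusteringResult:
    """Agglomerative clustering of |alpha| rows with a flat cut.

    Defaults: Euclidean distance, average linkage.  The flat labels at k
    clusters always refine the labels at k-1 (they are cuts of one tree).
    """
    if n_clusters < 1:
        raise DataValidationError("n_clusters must be >= 1")
    if n_clusters > activity.n_factors:
        raise DataValidationError("more clusters requested than profiles")
    if np.isnan(activity.alpha).any():
        raise DataValidationError("profiles must be complete for clustering")
    X = np.abs(activity.alpha)
    if activity.n_factors == 1:
        return ClusteringResult(activity.tf_ids, np.empty((0, 4)),
                                np.array([1]), 1, metric, method)
    Z = linkage(pdist(X, metric=metric), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusteringResult(tf_ids=activity.tf_ids, linkage_matrix=Z,
                            labels=labels, n_clusters=n_clusters,
                            metric=metric, method=method)


def cluster_mean_profile(activity: ActivityMatrix,
                         member_ids: list[str]) -> np.ndarray:
    """Elementwise mean of the |alpha| rows of the given members."""
    if not member_ids:
        raise DataValidationError("empty member set")
    rows = [np.abs(activity.row(tf)) for tf in member_ids]
    return np.mean(rows, axis=0)
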