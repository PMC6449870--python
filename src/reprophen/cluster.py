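"""Phenotype clustering of knockdown feature profiles.

Knockdowns (rows) are partitioned by K-means in the retained-feature Z-score
space; features (columns) are ordered by Euclidean average-linkage
hierarchical clustering for heatmap display. A cluster report counts control
wells per cluster and flags the cluster holding the majority of nt controls
as the reference ("normal reprogramming") phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

__all__ = ["ClusterAssignment", "cluster_knockdowns", "cluster_features",
           "summarize_clusters"]


@dataclass
class ClusterAssignment:
    labels: pd.Series            # target -> cluster id (1..k)
    k: int
    centroids: pd.DataFrame      # cluster id x features
    inertia: float               # within-cluster sum of squares
    feature_order: list[str] | None = None


def cluster_knockdowns(profiles: pd.DataFrame, k: int = 5, seed: int = 0,
                       n_init: int = 10) -> ClusterAssignment:
    """K-means (k-means++, ``n_init`` restarts) on feature Z-profiles."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(profiles) <= k:
        raise ValueError(f"k={k} requires more than k targets "
                         f"(got {len(profiles)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(profiles.values)
    labels = pd.Series(raw + 1, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_,
                             index=np.arange(1, k + 1),
                             columns=profiles.columns)
    return ClusterAssignment(labels, k, centroids, float(km.inertia_))


def cluster_features(profiles: pd.DataFrame
                     ) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of feature columns (Euclidean, average link).

    Returns the scipy linkage matrix and the dendrogram leaf order.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 features")
    Z = linkage(profiles.values.T, method="average", metric="euclidean")
    order = [profiles.columns[i] for i in leaves_list(Z)]
    return Z, order


def summarize_clusters(assignment: ClusterAssignment, roles: pd.Series
                       ) -> tuple[pd.DataFrame, int | None]:
    """Per-cluster size, centroid and control composition.

    Returns ``(report, reference_cluster)`` where ``reference_cluster`` is
    the cluster containing the most nt controls (None, with a warning, if no
    nt controls are present).
    """
    roles = roles.reindex(assignment.labels.index)
    rows = []
    for c in range(1, assignment.k + 1):
        members = assignment.labels.index[assignment.labels == c]
        r = roles.loc[members]
        row = {"cluster": c, "size": len(members),
               "n_nt": int((r == "nt").sum()),
               "n_positive": int((r == "positive").sum())}
        for name in sorted(members[r == "positive"]):
            row[f"has_{name}"] = True
        rows.append(row)
    report = pd.DataFrame(rows).set_index("cluster")
    flag_cols = [c for c in report.columns if c.startswith("has_")]
    if flag_cols:
        report[flag_cols] = report[flag_cols].notna() & \
            report[flag_cols].eq(True)
    if report["n_nt"].sum() == 0:
        warnings.warn("no nt controls present; reference cluster not flagged",
                      RuntimeWarning, stacklevel=2)
        reference = None
    else:
        reference = int(report["n_nt"].idxmax())
    report["reference"] = report.index == reference
    return report, reference
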