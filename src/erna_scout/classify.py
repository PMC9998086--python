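"""Unsupervised disease-state classification from eRNA expression.

Samples are clustered on row z-scored region expression with average-linkage
agglomerative clustering on the 1 - Pearson correlation distance, cut into
k clusters (k=2 for a two-cohort design), and compared to the known cohort
labels by the minimum misclassification count over all bijective
cluster-to-cohort assignments (the only label-symmetric definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

__all__ = ["zscore_rows", "correlation_cluster", "misclassification_count", "ClusteringResult"]


def zscore_rows(m: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Scale each row to mean 0, SD 1 (sample SD, n-1); constant rows -> 0."""
    x = np.asarray(m, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z = np.where(sd > 0, z, 0.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(z, index=m.index, columns=m.columns)
    return z


@dataclass
class ClusteringResult:
    linkage: np.ndarray          # scipy linkage matrix (merge order + heights)
    labels: pd.Series            # cluster id per sample (1..k)
    distance: pd.DataFrame       # sample x sample 1 - Pearson r
    misclassified_count: int | None = None


def correlation_cluster(m: pd.DataFrame, k: int = 2, method: str = "average") -> ClusteringResult:
    """Hierarchical clustering of samples (columns) on 1 - Pearson distance.

    Rows are z-scored first so r equals the covariance of scaled profiles.
    """
    if m.shape[1] < max(2, k):
        raise ValueError(f"need at least {max(2, k)} samples")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    z = np.asarray(zscore_rows(m), dtype=float)
    r = np.corrcoef(z, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrise against float noise
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusteringResult(
        linkage=link,
        labels=pd.Series(labels, index=m.columns, name="cluster"),
        distance=pd.DataFrame(d, index=m.columns, columns=m.columns),
    )


def misclassification_count(cluster_labels, cohort_labels) -> int:
    """Minimum misclassified samples over bijective cluster->cohort maps."""
    cl = pd.Series(cluster_labels)
    co = pd.Series(cohort_labels)
    if len(cl) != len(co):
        raise ValueError("label vectors differ in length")
    clusters = sorted(cl.unique().tolist())
    cohorts = sorted(co.unique().tolist())
    if len(clusters) != len(cohorts):
        raise ValueError(
            f"{len(clusters)} clusters vs {len(cohorts)} cohort labels: "
            "bijective assignment undefined"
        )
    conf = np.zeros((len(clusters), len(cohorts)), dtype=int)
    for c, h in zip(cl, co):
        conf[clusters.index(c), cohorts.index(h)] += 1
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return int(len(cl) - conf[rows, cols].sum())
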