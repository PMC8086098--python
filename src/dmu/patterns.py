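"""Binary missingness patterns and hierarchical clustering of rows.

Rows are clustered on the 0/1 missingness indicator matrix (0 = missing,
1 = observed), so only the *pattern* of missingness drives the grouping,
never the magnitude of the observed values.  The outcome column is always
fully observed and therefore excluded: it carries no pattern information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data import TabularDataset

__all__ = [
    "BinaryPatternMatrix",
    "RowClustering",
    "binarize_missingness",
    "build_linkage",
    "cluster_rows",
]

_LINKAGES = ("complete", "average", "ward")
_METRICS = ("euclidean", "jaccard")


@dataclass
class BinaryPatternMatrix:
    """0/1 encoding of the missingness pattern of a predictor matrix."""

    values: np.ndarray  # n x p over {0, 1}
    row_ids: np.ndarray  # original row indices

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RowClustering:
    """A flat cut of the hierarchical merge tree into at most ``k`` groups."""

    k: int
    labels: np.ndarray  # length n, values in 1..k
    linkage_record: np.ndarray  # scipy linkage matrix (merge heights + pairs)

    def cluster_indices(self) -> dict[int, np.ndarray]:
        order = np.argsort(self.labels, kind="stable")
        groups: dict[int, np.ndarray] = {}
        for lab in np.unique(self.labels):
            groups[int(lab)] = np.flatnonzero(self.labels == lab)
        return groups


def binarize_missingness(data: TabularDataset) -> BinaryPatternMatrix:
    """Map the predictor matrix to {0, 1}: zero marks a missing cell."""
    return BinaryPatternMatrix(
        values=data.mask.astype(np.int8),
        row_ids=np.arange(data.n),
    )


def build_linkage(
    bin_matrix: BinaryPatternMatrix,
    method: str = "complete",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerate the binary rows once; flat cuts at any ``k`` reuse this.

    Separating tree construction from the cut matters for hyperparameter
    search: the merge tree is identical for every ``k``.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    x = bin_matrix.values.astype(float)
    if x.shape[0] == 1:
        return np.empty((0, 4))
    if metric == "jaccard":
        d = pdist(bin_matrix.values.astype(bool), metric="jaccard")
        d = np.nan_to_num(d, nan=0.0)  # all-zero row pairs: define as identical
        return linkage(d, method=method)
    if method == "ward":
        return linkage(x, method="ward")
    return linkage(pdist(x, metric="euclidean"), method=method)


def cluster_rows(
    bin_matrix: BinaryPatternMatrix,
    k: int,
    method: str = "complete",
    metric: str = "euclidean",
    linkage_matrix: np.ndarray | None = None,
) -> RowClustering:
    """Cut the merge tree into at most ``k`` flat clusters.

    Ties in merge heights (common on binary data) can make the cut return
    fewer than ``k`` distinct groups; that is permitted.
    """
    n = bin_matrix.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows n={n}")
    if linkage_matrix is None:
        linkage_matrix = build_linkage(bin_matrix, method=method, metric=metric)
    if n == 1 or k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(linkage_matrix, t=k, criterion="maxclust")
    return RowClustering(k=k, labels=np.asarray(labels, dtype=int), linkage_record=linkage_matrix)
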