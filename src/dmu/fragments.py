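"""Fragmenting a missing-data table into complete, row-disjoint sub-datasets.

Each cluster of rows becomes a candidate sub-dataset by keeping exactly the
predictor columns observed in *every* row of the cluster (columns are
dropped, never rows), which guarantees completeness and keeps the clusters
row-disjoint.  A usability constraint then discards fragments whose sample
size is too small relative to their retained predictor count: a fragment
with s rows and q predictors is kept only when s / (q + 1) >= min_ratio,
the +1 accounting for the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TabularDataset
from .patterns import RowClustering

__all__ = ["SubDataset", "Fragmentation", "FragmentationError", "fragment", "validate_fragmentation"]


class FragmentationError(ValueError):
    """A structural violation (overlap or missing cells) in a fragmentation."""


@dataclass
class SubDataset:
    """A fully observed fragment: s rows by q retained predictors."""

    row_ids: np.ndarray
    columns: list[str]
    col_idx: np.ndarray
    predictors: np.ndarray  # s x q, complete
    outcome: np.ndarray  # length s

    @property
    def s(self) -> int:
        return self.predictors.shape[0]

    @property
    def q(self) -> int:
        return self.predictors.shape[1]


@dataclass
class Fragmentation:
    """Ordered kept fragments plus a record of rejected clusters."""

    subdatasets: list[SubDataset]
    skipped: list[dict] = field(default_factory=list)
    n_rows_total: int = 0

    @property
    def rows_used(self) -> int:
        return int(sum(sd.s for sd in self.subdatasets))

    @property
    def rows_discarded(self) -> int:
        return self.n_rows_total - self.rows_used


def fragment(
    data: TabularDataset,
    clustering: RowClustering,
    min_ratio: float = 2.0,
    order: str = "breadth_asc",
) -> Fragmentation:
    """Turn a row clustering into usable complete sub-datasets.

    Parameters
    ----------
    min_ratio:
        Minimum sample-to-parameter ratio ``s / (q + 1)`` for a fragment to
        be kept (default 2).
    order:
        Processing order of the kept fragments for the sequential update:
        ``breadth_asc`` (default) fits fragments with few retained predictors
        first and the widest fragments last, so the final belief of every
        coefficient comes from the least-marginal conditional model available
        and narrow fragments act only as priors; ``size_desc`` /
        ``size_asc`` order by sample size; ``index`` by original row position.
    """
    if data.n == 0:
        raise ValueError("empty training data")
    if clustering.labels.shape[0] != data.n:
        raise ValueError("clustering does not cover all rows of the data")
    if order not in ("breadth_asc", "size_desc", "size_asc", "index"):
        raise ValueError(f"unknown order {order!r}")

    observed = data.mask.astype(bool)
    kept: list[SubDataset] = []
    skipped: list[dict] = []
    for lab in np.unique(clustering.labels):
        rows = np.flatnonzero(clustering.labels == lab)
        cols = observed[rows].all(axis=0)
        q = int(cols.sum())
        s = rows.size
        if q < 1:
            skipped.append({"cluster": int(lab), "s": s, "q": q, "reason": "no fully observed predictor"})
            continue
        if s / (q + 1) < min_ratio:
            skipped.append(
                {
                    "cluster": int(lab),
                    "s": s,
                    "q": q,
                    "reason": f"usability constraint s/(q+1) = {s}/{q + 1} < {min_ratio}",
                }
            )
            continue
        col_idx = np.flatnonzero(cols)
        kept.append(
            SubDataset(
                row_ids=rows,
                columns=[data.column_names[j] for j in col_idx],
                col_idx=col_idx,
                predictors=data.predictors[np.ix_(rows, col_idx)].copy(),
                outcome=data.outcome[rows].copy(),
            )
        )

    if order == "breadth_asc":
        kept.sort(key=lambda sd: (sd.q, sd.s, int(sd.row_ids.min())))
    elif order == "size_desc":
        kept.sort(key=lambda sd: (-sd.s, int(sd.row_ids.min())))
    elif order == "size_asc":
        kept.sort(key=lambda sd: (sd.s, int(sd.row_ids.min())))
    else:
        kept.sort(key=lambda sd: int(sd.row_ids.min()))
    return Fragmentation(subdatasets=kept, skipped=skipped, n_rows_total=data.n)


def validate_fragmentation(frag: Fragmentation) -> dict:
    """Assert completeness and pairwise row-disjointness of the fragments.

    Returns a small report; raises :class:`FragmentationError` naming the
    offending pair (or fragment) on violation.
    """
    seen: dict[int, int] = {}
    for l, sd in enumerate(frag.subdatasets):
        if np.isnan(sd.predictors).any():
            raise FragmentationError(f"sub-dataset {l} contains missing values")
        for r in sd.row_ids:
            if int(r) in seen:
                raise FragmentationError(
                    f"sub-datasets {seen[int(r)]} and {l} overlap on row {int(r)}"
                )
            seen[int(r)] = l
    return {
        "n_subdatasets": len(frag.subdatasets),
        "n_skipped": len(frag.skipped),
        "rows_used": frag.rows_used,
        "rows_discarded": frag.rows_discarded,
    }
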