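"""Core tabular container shared by every stage of the pipeline.

A :class:`TabularDataset` holds one fully observed continuous outcome and a
predictor matrix in which missing entries are encoded as ``NaN``.  The
missingness mask is derived from the predictor matrix, so the two can never
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TabularDataset"]


@dataclass
class TabularDataset:
    """Outcome vector plus predictor matrix with optional missing entries.

    Parameters
    ----------
    outcome:
        Length-``n`` float vector; must be fully observed.
    predictors:
        ``n x p`` float matrix; missing cells are ``NaN``.
    column_names:
        Predictor column identifiers, length ``p``.
    outcome_name:
        Name of the outcome column when written to CSV.
    """

    outcome: np.ndarray
    predictors: np.ndarray
    column_names: list[str] = field(default_factory=list)
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        self.predictors = np.atleast_2d(np.asarray(self.predictors, dtype=float))
        n, p = self.predictors.shape
        if n < 1 or p < 1:
            raise ValueError("dataset needs at least one row and one predictor")
        if self.outcome.shape[0] != n:
            raise ValueError(
                f"outcome length {self.outcome.shape[0]} != predictor rows {n}"
            )
        if np.isnan(self.outcome).any():
            raise ValueError("outcome must be fully observed (no NaN)")
        if not self.column_names:
            self.column_names = [f"x{j + 1}" for j in range(p)]
        if len(self.column_names) != p:
            raise ValueError("column_names length must match predictor count")

    @property
    def n(self) -> int:
        return self.predictors.shape[0]

    @property
    def p(self) -> int:
        return self.predictors.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """``n x p`` indicator matrix: 1 where observed, 0 where missing."""
        return (~np.isnan(self.predictors)).astype(np.int8)

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean selector of rows with no missing predictor."""
        return ~np.isnan(self.predictors).any(axis=1)

    def is_complete(self) -> bool:
        return not np.isnan(self.predictors).any()

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            outcome=self.outcome.copy(),
            predictors=self.predictors.copy(),
            column_names=list(self.column_names),
            outcome_name=self.outcome_name,
        )
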