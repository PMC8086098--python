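"""Comparator methods: mean imputation, complete-case OLS, chained-equation
predictive mean matching with Rubin pooling, and pluggable third-party
imputers (kNN).

Mean imputation is also the normalizer of the benchmark tables: every other
method's test MSE is reported relative to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import TabularDataset

__all__ = [
    "InfeasibleError",
    "LinearModel",
    "ImputedDatasets",
    "PooledLinearModel",
    "ols_fit",
    "mean_impute",
    "cca_regress",
    "pmm_impute",
    "pooled_regress",
    "KNNImputerBaseline",
    "impute_then_regress",
]


class InfeasibleError(ValueError):
    """A method cannot be applied to this dataset (e.g. CCA without complete rows)."""


@dataclass
class LinearModel:
    intercept: float
    coef: np.ndarray
    columns: list[str]

    def predict(self, data: TabularDataset) -> np.ndarray:
        if data.column_names != self.columns:
            raise ValueError("column schema mismatch")
        return self.intercept + data.predictors @ self.coef


@dataclass
class ImputedDatasets:
    """m completed copies of one incomplete table."""

    datasets: list[TabularDataset]
    method: str
    rng_seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass
class PooledLinearModel:
    """Rubin-pooled OLS over multiply imputed datasets.

    total_var = within_var + (1 + 1/m) * between_var, per coefficient
    (intercept first).
    """

    intercept: float
    coef: np.ndarray
    columns: list[str]
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    m: int

    def predict(self, data: TabularDataset) -> np.ndarray:
        if data.column_names != self.columns:
            raise ValueError("column schema mismatch")
        return self.intercept + data.predictors @ self.coef


def ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with intercept; returns [b0, b1..bp]."""
    W = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(W, y, rcond=None)
    return coef


def _ols_cov(X: np.ndarray, y: np.ndarray, coef: np.ndarray) -> np.ndarray:
    W = np.column_stack([np.ones(len(y)), X])
    resid = y - W @ coef
    dof = max(len(y) - W.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX = W.T @ W
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise InfeasibleError("rank-deficient design in OLS fit")
    return sigma2 * np.linalg.inv(XtX)


def mean_impute(data: TabularDataset) -> TabularDataset:
    """Fill each missing cell with the observed mean of its column."""
    out = data.copy()
    for j, name in enumerate(data.column_names):
        col = out.predictors[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise InfeasibleError(f"column {name!r} has no observed value to average")
        if miss.any():
            col[miss] = col[~miss].mean()
    return out


def cca_regress(data: TabularDataset) -> LinearModel:
    """Complete-case analysis: OLS on the rows without any missing entry."""
    rows = data.complete_rows
    n_complete = int(rows.sum())
    if n_complete < data.p + 2:
        raise InfeasibleError(
            f"complete-case analysis needs at least p+2={data.p + 2} complete "
            f"rows, found {n_complete}"
        )
    coef = ols_fit(data.predictors[rows], data.outcome[rows])
    return LinearModel(intercept=float(coef[0]), coef=coef[1:], columns=list(data.column_names))


def _pmm_single(
    data: TabularDataset,
    k_donors: int,
    n_cycles: int,
    rng: np.random.Generator,
    use_outcome: bool,
) -> np.ndarray:
    X = data.predictors.copy()
    observed = ~np.isnan(data.predictors)
    cols_missing = [j for j in range(data.p) if not observed[:, j].all()]

    # initialize missing cells with random draws from the observed values
    for j in cols_missing:
        obs_vals = data.predictors[observed[:, j], j]
        miss = ~observed[:, j]
        X[miss, j] = rng.choice(obs_vals, size=int(miss.sum()), replace=True)

    for _ in range(n_cycles):
        for j in cols_missing:
            obs = observed[:, j]
            mis = ~obs
            others = np.delete(X, j, axis=1)
            if use_outcome:
                Z = np.column_stack([np.ones(data.n), others, data.outcome])
            else:
                Z = np.column_stack([np.ones(data.n), others])
            target = data.predictors[obs, j]
            coef, *_ = np.linalg.lstsq(Z[obs], target, rcond=None)
            pred = Z @ coef
            pred_obs, pred_mis = pred[obs], pred[mis]
            if not np.all(np.isfinite(pred)):
                warnings.warn(f"degenerate imputation regression for column {j}; random donors used")
                X[mis, j] = rng.choice(target, size=int(mis.sum()), replace=True)
                continue
            # donor search: k nearest observed predictions per missing cell
            diff = np.abs(pred_mis[:, None] - pred_obs[None, :])
            kk = min(k_donors, pred_obs.size)
            donor_pool = np.argpartition(diff, kk - 1, axis=1)[:, :kk]
            pick = rng.integers(0, kk, size=donor_pool.shape[0])
            donors = donor_pool[np.arange(donor_pool.shape[0]), pick]
            X[mis, j] = target[donors]
    return X


def pmm_impute(
    data: TabularDataset,
    m: int = 5,
    k_donors: int = 5,
    n_cycles: int = 5,
    rng: np.random.Generator | int | None = None,
    use_outcome: bool = False,
) -> ImputedDatasets:
    """Chained-equations predictive mean matching.

    Each incomplete column is regressed on the other predictor columns at
    their current completions; each missing cell then copies the observed
    value of one of the ``k_donors`` rows whose predicted values are closest.
    ``m`` independent completed tables are produced.  ``use_outcome`` adds
    the outcome to the imputation models (the convention of some multiple-
    imputation toolchains); the default imputes from predictors only.
    """
    seed = rng if isinstance(rng, int) else 0
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    observed = ~np.isnan(data.predictors)
    for j, name in enumerate(data.column_names):
        if observed[:, j].sum() < k_donors:
            raise InfeasibleError(
                f"column {name!r} has fewer than k_donors={k_donors} observed values"
            )
    datasets = []
    for _ in range(m):
        X = _pmm_single(data, k_donors, n_cycles, rng, use_outcome)
        datasets.append(
            TabularDataset(
                outcome=data.outcome.copy(),
                predictors=X,
                column_names=list(data.column_names),
                outcome_name=data.outcome_name,
            )
        )
    return ImputedDatasets(datasets=datasets, method="pmm", rng_seed=seed)


def pooled_regress(imp: ImputedDatasets) -> PooledLinearModel:
    """OLS per completed table, pooled by Rubin's rules."""
    if imp.m < 1:
        raise ValueError("need at least one imputed dataset")
    coefs, covs = [], []
    for ds in imp.datasets:
        coef = ols_fit(ds.predictors, ds.outcome)
        covs.append(np.diag(_ols_cov(ds.predictors, ds.outcome, coef)))
        coefs.append(coef)
    coefs = np.array(coefs)
    pooled = coefs.mean(axis=0)
    within = np.array(covs).mean(axis=0)
    if imp.m >= 2:
        between = coefs.var(axis=0, ddof=1)
    else:
        between = np.zeros_like(pooled)
    total = within + (1.0 + 1.0 / imp.m) * between
    cols = list(imp.datasets[0].column_names)
    return PooledLinearModel(
        intercept=float(pooled[0]),
        coef=pooled[1:],
        columns=cols,
        within_var=within,
        between_var=between,
        total_var=total,
        m=imp.m,
    )


class KNNImputerBaseline:
    """Thin adapter over scikit-learn's k-nearest-neighbours imputer."""

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit_transform(self, data: TabularDataset) -> TabularDataset:
        from sklearn.impute import KNNImputer

        imputer = KNNImputer(n_neighbors=self.n_neighbors)
        X = imputer.fit_transform(data.predictors)
        return TabularDataset(
            outcome=data.outcome.copy(),
            predictors=X,
            column_names=list(data.column_names),
            outcome_name=data.outcome_name,
        )


def impute_then_regress(data: TabularDataset, imputer) -> LinearModel:
    """Complete the table with ``imputer`` (fit_transform protocol), then OLS."""
    completed = imputer.fit_transform(data)
    coef = ols_fit(completed.predictors, completed.outcome)
    return LinearModel(intercept=float(coef[0]), coef=coef[1:], columns=list(data.column_names))
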