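"""Synthetic data generator for the missing-data regression study.

The generator produces tables from the linear model

    y = beta0 + 0.2 x1 + 0.3 x2 + 0.4 x3 + eps,   eps ~ N(0, 0.25)

with x1 ~ Beta(7, 2), x2 ~ U(0, 2) and x3..xp standard normal, coupled
through a Gaussian copula whose latent correlation matrix carries random
correlations in [-0.5, 0.5] among the first five predictors and zeros
elsewhere.  Missingness is introduced completely at random (MCAR),
independently per predictor cell; the outcome is never amputed.

Two training scenarios are supported: SCR ("some complete rows") appends a
block of fully observed rows after amputation, NCR ("no complete rows")
appends none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import TabularDataset

__all__ = [
    "ScenarioConfig",
    "build_correlation_matrix",
    "nearest_positive_definite",
    "generate_complete_data",
    "ampute_mcar",
    "build_scenario",
]

_EIG_FLOOR = 1e-6


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``beta`` defaults to (0.2, 0.3, 0.4, 0, ..., 0); ``n_complete_extra``
    distinguishes SCR (50) from NCR (0).
    """

    p: int = 20
    n_train: int = 3150
    n_complete_extra: int = 50
    n_test: int = 1000
    missing_rate: float = 0.80
    beta: np.ndarray | None = None
    beta0: float = 0.0
    noise_var: float = 0.25
    corr_range: tuple[float, float] = (-0.5, 0.5)
    seed: int = 0
    # predictors sharing random latent correlations (the first block)
    n_correlated: int = 5

    def __post_init__(self) -> None:
        if self.beta is None:
            b = np.zeros(self.p)
            b[:3] = (0.2, 0.3, 0.4)
            self.beta = b
        else:
            self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != self.p:
            raise ValueError("len(beta) must equal p")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        lo, hi = self.corr_range
        if not (-1.0 < lo <= hi < 1.0):
            raise ValueError("corr_range must be a sub-interval of (-1, 1)")


def nearest_positive_definite(corr: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped up, the matrix is rebuilt and
    rescaled back to unit diagonal.  A valid input passes through unchanged.
    """
    sym = 0.5 * (corr + corr.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eig_floor:
        return sym
    vals = np.clip(vals, eig_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return 0.5 * (repaired + repaired.T)


def build_correlation_matrix(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the latent correlation matrix of the scenario.

    Off-diagonal entries among the first ``n_correlated`` predictors are
    i.i.d. uniform on ``corr_range``; all other pairs are uncorrelated.  The
    raw draw is repaired to the nearest positive-definite correlation matrix
    when necessary.
    """
    if config.p < config.n_correlated:
        raise ValueError(
            f"p must be >= {config.n_correlated} (correlated block size)"
        )
    m = config.n_correlated
    corr = np.eye(config.p)
    lo, hi = config.corr_range
    block = np.eye(m)
    iu = np.triu_indices(m, k=1)
    draws = rng.uniform(lo, hi, size=len(iu[0]))
    block[iu] = draws
    block[(iu[1], iu[0])] = draws
    corr[:m, :m] = block
    return nearest_positive_definite(corr)


def _copula_transform(z: np.ndarray) -> np.ndarray:
    """Map latent standard-normal columns to the target marginals.

    Column 0 -> Beta(7, 2), column 1 -> Uniform(0, 2), the rest keep their
    standard-normal marginal (identity transform).
    """
    x = z.copy()
    u1 = stats.norm.cdf(z[:, 0])
    x[:, 0] = stats.beta.ppf(u1, 7, 2)
    x[:, 1] = 2.0 * stats.norm.cdf(z[:, 1])
    return x


def generate_complete_data(
    config: ScenarioConfig,
    corr: np.ndarray,
    n_rows: int,
    rng: np.random.Generator,
) -> TabularDataset:
    """Sample ``n_rows`` fully observed rows via the Gaussian copula."""
    vals = np.linalg.eigvalsh(0.5 * (corr + corr.T))
    if vals.min() <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_rows, config.p)) @ chol.T
    x = _copula_transform(z)
    eps = rng.normal(0.0, np.sqrt(config.noise_var), size=n_rows)
    y = config.beta0 + x @ config.beta + eps
    return TabularDataset(outcome=y, predictors=x)


def ampute_mcar(
    data: TabularDataset, missing_rate: float, rng: np.random.Generator
) -> TabularDataset:
    """Set each predictor cell missing independently with ``missing_rate``."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not data.is_complete():
        raise ValueError("ampute_mcar expects fully observed input")
    out = data.copy()
    if missing_rate > 0.0:
        drop = rng.random(out.predictors.shape) < missing_rate
        out.predictors[drop] = np.nan
    return out


def build_scenario(config: ScenarioConfig) -> tuple[TabularDataset, TabularDataset]:
    """Build one (train, test) pair for the configured scenario.

    Training data: ``n_train`` rows amputed at ``missing_rate``, followed by
    ``n_complete_extra`` freshly drawn fully observed rows (SCR) or none
    (NCR).  Test data: ``n_test`` fully observed rows from the same
    generator.  Everything is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    corr = build_correlation_matrix(config, rng)
    raw = generate_complete_data(config, corr, config.n_train, rng)
    train = ampute_mcar(raw, config.missing_rate, rng)
    if config.n_complete_extra > 0:
        extra = generate_complete_data(config, corr, config.n_complete_extra, rng)
        train = TabularDataset(
            outcome=np.concatenate([train.outcome, extra.outcome]),
            predictors=np.vstack([train.predictors, extra.predictors]),
            column_names=list(train.column_names),
            outcome_name=train.outcome_name,
        )
    test = generate_complete_data(config, corr, config.n_test, rng)
    return train, test
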