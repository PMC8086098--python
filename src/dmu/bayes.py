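"""Bayesian linear regression by Gibbs sampling, chained across fragments.

Each fragment is fitted with a semi-conjugate model: independent normal
priors per coefficient (intercept included) and a gamma prior on the noise
precision.  The Gibbs sampler alternates

  * coefficients | precision  ~  multivariate normal full conditional,
  * precision | coefficients  ~  gamma full conditional,

and the retained draws are summarized marginally — normal moment-matching
per coefficient and gamma moment-matching for the precision — so the
posterior stays inside the prior family and can serve verbatim as the prior
of the next fragment.  Coefficients absent from a fragment keep their
current belief untouched.

Default priors: beta_j ~ N(0, 100) for every coefficient and
sigma^-2 ~ Gamma(5/2, 50/2) (shape/rate), with 6000 MCMC iterations of
which the first 1000 are burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import TabularDataset
from .fragments import Fragmentation, SubDataset

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "INTERCEPT",
    "CoefficientBelief",
    "PrecisionBelief",
    "BeliefState",
    "McmcConfig",
    "default_beliefs",
    "gibbs_fit",
    "summarize_posterior",
    "dmu_fit",
    "predict",
]

INTERCEPT = "(intercept)"

DEFAULT_COEF_MEAN = 0.0
DEFAULT_COEF_VAR = 100.0
DEFAULT_PREC_SHAPE = 5.0 / 2.0
DEFAULT_PREC_RATE = 50.0 / 2.0

_VAR_FLOOR = 1e-10


@dataclass
class CoefficientBelief:
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("coefficient belief variance must be positive")


@dataclass
class PrecisionBelief:
    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("precision belief requires positive shape and rate")


@dataclass
class BeliefState:
    """Per-coefficient normal beliefs plus a gamma belief on precision."""

    coefficients: dict[str, CoefficientBelief]
    precision: PrecisionBelief
    history: list[dict] = field(default_factory=list)

    def copy(self) -> "BeliefState":
        return BeliefState(
            coefficients={
                c: CoefficientBelief(b.mean, b.variance)
                for c, b in self.coefficients.items()
            },
            precision=PrecisionBelief(self.precision.shape, self.precision.rate),
            history=list(self.history),
        )


@dataclass
class McmcConfig:
    n_iter: int = 6000
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")


def default_beliefs(columns: list[str]) -> BeliefState:
    """Initial beliefs: every coefficient N(0, 100), precision Gamma(5/2, 50/2)."""
    coefs = {INTERCEPT: CoefficientBelief(DEFAULT_COEF_MEAN, DEFAULT_COEF_VAR)}
    for c in columns:
        coefs[c] = CoefficientBelief(DEFAULT_COEF_MEAN, DEFAULT_COEF_VAR)
    return BeliefState(
        coefficients=coefs,
        precision=PrecisionBelief(DEFAULT_PREC_SHAPE, DEFAULT_PREC_RATE),
    )


@njit(cache=False)
def _gibbs_kernel(WtW, Wty, yty, n, prior_mean, prior_var, prec_shape, prec_rate, n_iter, burn_in, seed):
    """Semi-conjugate Gibbs sampler on sufficient statistics.

    Returns (coefficient draws, precision draws) after burn-in.
    """
    np.random.seed(seed)
    q = WtW.shape[0]
    prior_prec = 1.0 / prior_var
    shape_post = prec_shape + 0.5 * n
    n_keep = n_iter - burn_in
    coef_draws = np.empty((n_keep, q))
    prec_draws = np.empty(n_keep)
    tau = prec_shape / prec_rate
    for it in range(n_iter):
        # coefficient block | precision
        A = tau * WtW
        for j in range(q):
            A[j, j] += prior_prec[j]
        b = tau * Wty + prior_prec * prior_mean
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, b)
        z = np.random.standard_normal(q)
        beta = mu + np.linalg.solve(L.T, z)
        # precision | coefficients
        rss = yty - 2.0 * np.dot(beta, Wty) + np.dot(beta, WtW @ beta)
        if rss < 0.0:
            rss = 0.0
        tau = np.random.gamma(shape_post, 1.0 / (prec_rate + 0.5 * rss))
        if it >= burn_in:
            coef_draws[it - burn_in] = beta
            prec_draws[it - burn_in] = tau
    return coef_draws, prec_draws


def _prior_vectors(columns: list[str], state: BeliefState) -> tuple[np.ndarray, np.ndarray]:
    names = [INTERCEPT] + list(columns)
    means = np.array([state.coefficients[c].mean for c in names])
    variances = np.array([state.coefficients[c].variance for c in names])
    return means, variances


def gibbs_fit(
    sub: SubDataset,
    prior: BeliefState,
    mcmc: McmcConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fit one fragment; returns (coefficient draws, precision draws, names).

    The coefficient columns are ``[(intercept)] + sub.columns``.
    """
    if np.isnan(sub.predictors).any():
        raise ValueError("sub-dataset must be fully observed")
    W = np.column_stack([np.ones(sub.s), sub.predictors])
    WtW = W.T @ W
    Wty = W.T @ sub.outcome
    yty = float(sub.outcome @ sub.outcome)
    means, variances = _prior_vectors(sub.columns, prior)
    try:
        coef_draws, prec_draws = _gibbs_kernel(
            WtW,
            Wty,
            yty,
            sub.s,
            means,
            variances,
            prior.precision.shape,
            prior.precision.rate,
            mcmc.n_iter,
            mcmc.burn_in,
            int(mcmc.seed) % (2**31 - 1),
        )
    except Exception as exc:  # np.linalg.LinAlgError from a singular conditional
        raise ValueError(
            "Gibbs update failed (near-singular design); consider a larger "
            "min_ratio so fragments carry more rows per predictor"
        ) from exc
    return coef_draws, prec_draws, [INTERCEPT] + list(sub.columns)


def summarize_posterior(
    coef_draws: np.ndarray,
    prec_draws: np.ndarray,
    names: list[str],
) -> tuple[dict[str, CoefficientBelief], PrecisionBelief]:
    """Moment-match retained draws back into the belief families.

    Coefficients: marginal normal (sample mean / variance, floored at 1e-10).
    Precision: gamma by method of moments, shape = m^2/v, rate = m/v.
    """
    if coef_draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    means = coef_draws.mean(axis=0)
    variances = coef_draws.var(axis=0, ddof=1)
    if (variances < _VAR_FLOOR).any():
        warnings.warn("degenerate coefficient draws; variance clamped to floor")
        variances = np.maximum(variances, _VAR_FLOOR)
    coefs = {
        name: CoefficientBelief(float(m), float(v))
        for name, m, v in zip(names, means, variances)
    }
    pm = float(prec_draws.mean())
    pv = float(prec_draws.var(ddof=1))
    if pv <= 0:
        raise ValueError("zero-variance precision draws: sampler failure")
    precision = PrecisionBelief(shape=pm * pm / pv, rate=pm / pv)
    return coefs, precision


def dmu_fit(
    frag: Fragmentation,
    init: BeliefState,
    mcmc: McmcConfig,
    chain_precision: bool = True,
    chain_intercept: bool = False,
) -> BeliefState:
    """Sequential Bayesian updating over the fragments.

    Fragments are visited in fragmentation order; the fitted posterior of
    each fragment overwrites the beliefs of exactly the predictor
    coefficients present in it.  The chained set is the predictor
    coefficients beta_1..beta_p: the intercept's prior resets to its initial
    belief before every fragment (each fragment's marginal intercept absorbs
    the mean contribution of its absent predictors, so carrying it across
    fragments with different column sets would let incompatible intercepts
    fight each other; set ``chain_intercept`` to propagate it anyway).  With
    ``chain_precision`` false the noise precision likewise resets before
    every fragment.
    """
    state = init.copy()
    if not frag.subdatasets:
        warnings.warn("empty fragmentation: beliefs returned unchanged")
        return state
    init_precision = PrecisionBelief(init.precision.shape, init.precision.rate)
    init_intercept = CoefficientBelief(
        init.coefficients[INTERCEPT].mean, init.coefficients[INTERCEPT].variance
    )
    for i, sub in enumerate(frag.subdatasets):
        if not chain_precision:
            state.precision = PrecisionBelief(init_precision.shape, init_precision.rate)
        if not chain_intercept:
            state.coefficients[INTERCEPT] = CoefficientBelief(
                init_intercept.mean, init_intercept.variance
            )
        sub_mcmc = McmcConfig(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            seed=(int(mcmc.seed) + 7919 * (i + 1)) % (2**31 - 1),
        )
        coef_draws, prec_draws, names = gibbs_fit(sub, state, sub_mcmc)
        coefs, precision = summarize_posterior(coef_draws, prec_draws, names)
        state.coefficients.update(coefs)
        state.precision = precision
        state.history.append(
            {
                "fragment": i,
                "s": sub.s,
                "columns": list(sub.columns),
                "posterior_means": {c: coefs[c].mean for c in names},
                "precision": {"shape": precision.shape, "rate": precision.rate},
            }
        )
    return state


def predict(state: BeliefState, test: TabularDataset) -> np.ndarray:
    """Plug-in prediction from posterior means on a fully observed table."""
    if not test.is_complete():
        raise ValueError("prediction requires a fully observed table")
    missing = [c for c in test.column_names if c not in state.coefficients]
    if missing:
        raise ValueError(f"beliefs lack columns {missing}: schema mismatch")
    coef = np.array([state.coefficients[c].mean for c in test.column_names])
    return state.coefficients[INTERCEPT].mean + test.predictors @ coef
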