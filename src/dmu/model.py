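"""High-level fit/predict interface tying clustering, fragmentation,
sequential updating and k-selection together."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bayes import (
    INTERCEPT,
    BeliefState,
    CoefficientBelief,
    McmcConfig,
    PrecisionBelief,
    default_beliefs,
    dmu_fit,
    predict,
)
from .data import TabularDataset
from .fragments import fragment
from .patterns import binarize_missingness, cluster_rows
from .selection import FitnessEvaluator, GAConfig, GAResult, minimize_int_ga, select_k_exhaustive

__all__ = ["DMUModel", "fit_dmu"]


@dataclass
class DMUModel:
    """A fitted dynamic-model-updating regressor."""

    beliefs: BeliefState
    k: int
    columns: list[str]
    selection: GAResult | None = None
    config: dict = field(default_factory=dict)

    def predict(self, test: TabularDataset) -> np.ndarray:
        return predict(self.beliefs, test)

    def mse(self, test: TabularDataset) -> float:
        return float(np.mean((self.predict(test) - test.outcome) ** 2))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "columns": self.columns,
            "config": self.config,
            "coefficients": {
                c: {"mean": b.mean, "variance": b.variance}
                for c, b in self.beliefs.coefficients.items()
            },
            "precision": {
                "shape": self.beliefs.precision.shape,
                "rate": self.beliefs.precision.rate,
            },
            "history": self.beliefs.history,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "DMUModel":
        beliefs = BeliefState(
            coefficients={
                c: CoefficientBelief(v["mean"], v["variance"])
                for c, v in d["coefficients"].items()
            },
            precision=PrecisionBelief(d["precision"]["shape"], d["precision"]["rate"]),
            history=d.get("history", []),
        )
        return cls(
            beliefs=beliefs,
            k=d["k"],
            columns=list(d["columns"]),
            config=d.get("config", {}),
        )

    @classmethod
    def load(cls, path) -> "DMUModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _internal_holdout(
    train: TabularDataset, fraction: float, seed: int
) -> tuple[TabularDataset, TabularDataset]:
    """Split fully observed training rows off as a validation table."""
    complete = np.flatnonzero(train.complete_rows)
    n_hold = int(round(fraction * complete.size))
    if n_hold < 10:
        raise ValueError(
            "too few complete rows for an internal holdout; pass an external "
            "validation table instead"
        )
    rng = np.random.default_rng(seed)
    hold = rng.choice(complete, size=n_hold, replace=False)
    keep = np.setdiff1d(np.arange(train.n), hold)
    mk = lambda idx: TabularDataset(
        outcome=train.outcome[idx],
        predictors=train.predictors[idx],
        column_names=list(train.column_names),
        outcome_name=train.outcome_name,
    )
    return mk(keep), mk(hold)


def fit_dmu(
    train: TabularDataset,
    k: int | None = None,
    holdout: TabularDataset | None = None,
    selection: str = "ga",
    mcmc: McmcConfig | None = None,
    ga: GAConfig | None = None,
    linkage_method: str = "complete",
    metric: str = "euclidean",
    min_ratio: float = 2.0,
    order: str = "breadth_asc",
    chain_precision: bool = True,
    chain_intercept: bool = False,
    seed: int = 0,
) -> DMUModel:
    """Fit a DMU regressor, selecting k if it is not supplied.

    With ``k`` given, the table is clustered once at that k and fitted.
    Otherwise k is chosen by ``selection`` ("ga" or "exhaustive") using RMSE
    on ``holdout``; when no holdout is given, a fraction of the complete
    training rows (``ga.fitness_holdout``) is split off for that purpose.
    """
    mcmc = mcmc or McmcConfig(seed=seed)
    ga = ga or GAConfig(seed=seed)
    config = {
        "linkage": linkage_method,
        "metric": metric,
        "min_ratio": min_ratio,
        "order": order,
        "chain_precision": chain_precision,
        "chain_intercept": chain_intercept,
    }

    if k is not None:
        bin_matrix = binarize_missingness(train)
        clustering = cluster_rows(bin_matrix, k, method=linkage_method, metric=metric)
        frag = fragment(train, clustering, min_ratio=min_ratio, order=order)
        state = dmu_fit(
            frag, default_beliefs(train.column_names), mcmc, chain_precision, chain_intercept
        )
        return DMUModel(beliefs=state, k=k, columns=list(train.column_names), config=config)

    fit_train = train
    if holdout is None:
        frac = ga.fitness_holdout if isinstance(ga.fitness_holdout, float) else 0.2
        fit_train, holdout = _internal_holdout(train, frac, seed)

    evaluator = FitnessEvaluator(
        fit_train,
        holdout,
        mcmc=mcmc,
        linkage_method=linkage_method,
        metric=metric,
        min_ratio=min_ratio,
        order=order,
        chain_precision=chain_precision,
        chain_intercept=chain_intercept,
    )
    k_max = min(ga.k_max or fit_train.n, fit_train.n)
    if selection == "exhaustive":
        result = select_k_exhaustive(evaluator, range(ga.k_min, k_max + 1))
    elif selection == "ga":
        result = minimize_int_ga(evaluator, ga, k_max)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    best_state = evaluator.states[result.best_k]
    return DMUModel(
        beliefs=best_state,
        k=result.best_k,
        columns=list(train.column_names),
        selection=result,
        config=config,
    )
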