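"""Choosing the number of subgroups k by exhaustive sweep or genetic search.

The fitness of a candidate k is the RMSE of the chained Bayesian model built
at that k, evaluated on a fully observed holdout table.  The merge tree is
built once per training table and only the flat cut varies with k, so a
fitness evaluation costs one fragmentation plus one sequential fit.  A k at
which no fragment survives the usability constraint is infeasible and scores
+inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bayes import BeliefState, McmcConfig, default_beliefs, dmu_fit, predict
from .data import TabularDataset
from .fragments import fragment
from .patterns import binarize_missingness, build_linkage, cluster_rows

__all__ = [
    "GAConfig",
    "GAResult",
    "FitnessEvaluator",
    "fitness",
    "select_k_exhaustive",
    "select_k_ga",
    "minimize_int_ga",
]


@dataclass
class GAConfig:
    """Genetic-algorithm budget and operator rates for the search over k."""

    k_min: int = 1
    k_max: int | None = None  # None -> number of training rows
    pop_size: int = 20
    n_generations: int = 15
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_count: int = 2
    seed: int = 0
    fitness_holdout: float | str = 0.2

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GAResult:
    best_k: int
    best_fitness: float
    trace: list[list[tuple[int, float]]]
    evaluations: dict[int, float] = field(default_factory=dict)


class FitnessEvaluator:
    """Memoized RMSE fitness of k on a fixed (train, holdout) pair.

    Builds the missingness-pattern linkage once; caches fitted beliefs per k
    so the selected model never needs refitting.
    """

    def __init__(
        self,
        train: TabularDataset,
        holdout: TabularDataset,
        mcmc: McmcConfig | None = None,
        linkage_method: str = "complete",
        metric: str = "euclidean",
        min_ratio: float = 2.0,
        order: str = "breadth_asc",
        chain_precision: bool = True,
        chain_intercept: bool = False,
    ) -> None:
        self.train = train
        self.holdout = holdout
        self.mcmc = mcmc or McmcConfig()
        self.linkage_method = linkage_method
        self.metric = metric
        self.min_ratio = min_ratio
        self.order = order
        self.chain_precision = chain_precision
        self.chain_intercept = chain_intercept
        self._bin = binarize_missingness(train)
        self._linkage = build_linkage(self._bin, method=linkage_method, metric=metric)
        self.cache: dict[int, float] = {}
        self.states: dict[int, BeliefState] = {}
        self.n_calls = 0  # number of *non-memoized* evaluations

    def fit_at_k(self, k: int) -> BeliefState:
        clustering = cluster_rows(self._bin, k, linkage_matrix=self._linkage)
        frag = fragment(
            self.train, clustering, min_ratio=self.min_ratio, order=self.order
        )
        if not frag.subdatasets:
            raise _Infeasible
        init = default_beliefs(self.train.column_names)
        return dmu_fit(
            frag,
            init,
            self.mcmc,
            chain_precision=self.chain_precision,
            chain_intercept=self.chain_intercept,
        )

    def __call__(self, k: int) -> float:
        k = int(k)
        if not (1 <= k <= self.train.n):
            raise ValueError(f"k={k} outside [1, n={self.train.n}]")
        if k in self.cache:
            return self.cache[k]
        self.n_calls += 1
        try:
            state = self.fit_at_k(k)
        except _Infeasible:
            self.cache[k] = math.inf
            return math.inf
        yhat = predict(state, self.holdout)
        rmse = float(np.sqrt(np.mean((yhat - self.holdout.outcome) ** 2)))
        self.cache[k] = rmse
        self.states[k] = state
        return rmse


class _Infeasible(Exception):
    pass


def fitness(
    k: int,
    train: TabularDataset,
    holdout: TabularDataset,
    **kwargs,
) -> float:
    """One-shot RMSE fitness of k (convenience over :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(train, holdout, **kwargs)(k)


def _best_of(evaluations: dict[int, float]) -> tuple[int, float]:
    # ties broken toward the smallest k (cheapest model)
    best_k = min(evaluations, key=lambda k: (evaluations[k], k))
    return best_k, evaluations[best_k]


def select_k_exhaustive(
    fn,
    k_values,
) -> GAResult:
    """Evaluate ``fn`` at every k in ``k_values`` and take the argmin.

    ``fn`` is any fitness callable (typically a :class:`FitnessEvaluator`).
    """
    evaluations = {int(k): fn(int(k)) for k in k_values}
    best_k, best_f = _best_of(evaluations)
    if math.isinf(best_f):
        raise ValueError("no feasible k in the supplied range")
    return GAResult(
        best_k=best_k,
        best_fitness=best_f,
        trace=[sorted(evaluations.items())],
        evaluations=evaluations,
    )


def minimize_int_ga(fn, ga: GAConfig, k_max: int) -> GAResult:
    """Genetic minimization of an integer-argument fitness function.

    Candidates are binary-encoded integers mapped into [k_min, k_max] by
    modulus; operators are tournament selection (size 2), single-point
    crossover, independent per-bit flip mutation, and elitism.  All
    evaluations are memoized, so the reported best is the minimum over every
    k ever evaluated.
    """
    k_min = ga.k_min
    span = k_max - k_min + 1
    nbits = max(1, int(math.ceil(math.log2(span))) or 1)
    rng = np.random.default_rng(ga.seed)
    memo: dict[int, float] = {}

    def decode(g: int) -> int:
        return k_min + (int(g) % span)

    def evaluate(g: int) -> float:
        k = decode(g)
        if k not in memo:
            memo[k] = fn(k)
        return memo[k]

    pop = rng.integers(0, 2**nbits, size=ga.pop_size).tolist()
    trace: list[list[tuple[int, float]]] = []
    fits = [evaluate(g) for g in pop]
    trace.append([(decode(g), f) for g, f in zip(pop, fits)])

    for _ in range(ga.n_generations):
        ranked = sorted(zip(pop, fits), key=lambda t: (t[1], decode(t[0])))
        elites = [g for g, _ in ranked[: ga.elitism_count]]
        children: list[int] = list(elites)
        while len(children) < ga.pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, ga.pop_size, size=2)
                a, b = (pop[i], fits[i]), (pop[j], fits[j])
                parents.append(a[0] if (a[1], decode(a[0])) <= (b[1], decode(b[0])) else b[0])
            c1, c2 = parents
            if nbits > 1 and rng.random() < ga.crossover_prob:
                point = int(rng.integers(1, nbits))
                lower = (1 << point) - 1
                c1, c2 = (c1 & ~lower) | (c2 & lower), (c2 & ~lower) | (c1 & lower)
            for child in (c1, c2):
                for bit in range(nbits):
                    if rng.random() < ga.mutation_prob:
                        child ^= 1 << bit
                children.append(child)
        pop = children[: ga.pop_size]
        fits = [evaluate(g) for g in pop]
        trace.append([(decode(g), f) for g, f in zip(pop, fits)])

    best_k, best_f = _best_of(memo)
    if math.isinf(best_f):
        raise ValueError("genetic search found no feasible k")
    return GAResult(best_k=best_k, best_fitness=best_f, trace=trace, evaluations=memo)


def select_k_ga(
    train: TabularDataset,
    holdout: TabularDataset,
    ga: GAConfig,
    evaluator: FitnessEvaluator | None = None,
    **kwargs,
) -> tuple[GAResult, FitnessEvaluator]:
    """Genetic search for k on a training table; returns result + evaluator."""
    if evaluator is None:
        evaluator = FitnessEvaluator(train, holdout, **kwargs)
    k_max = ga.k_max if ga.k_max is not None else train.n
    k_max = min(k_max, train.n)
    result = minimize_int_ga(evaluator, ga, k_max)
    return result, evaluator
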