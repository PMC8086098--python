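import numpy as np
import pytest
from scipy import stats

from dmu import (
    INTERCEPT,
    BeliefState,
    CoefficientBelief,
    McmcConfig,
    PrecisionBelief,
    TabularDataset,
    default_beliefs,
    dmu_fit,
    gibbs_fit,
    predict,
    summarize_posterior,
)
from dmu.baselines import ols_fit
from dmu.fragments import Fragmentation, SubDataset


def _sub(X, y, columns=None):
    X = np.atleast_2d(X)
    columns = columns or [f"x{j + 1}" for j in range(X.shape[1])]
    return SubDataset(
        row_ids=np.arange(len(y)),
        columns=columns,
        col_idx=np.arange(X.shape[1]),
        predictors=X,
        outcome=np.asarray(y, float),
    )


def _beliefs(columns, mean=0.0, var=100.0, shape=2.5, rate=25.0):
    state = default_beliefs(columns)
    for c in state.coefficients:
        state.coefficients[c] = CoefficientBelief(mean, var)
    state.precision = PrecisionBelief(shape, rate)
    return state


def exact_posterior_mean(W, y, m0, v0, a0, b0, grid_size=400):
    """Numeric oracle: exact posterior coefficient mean of the semi-conjugate
    model by one-dimensional quadrature over the noise precision.

    p(tau | y) is proportional to the gamma prior times the marginal normal
    likelihood N(y; W m0, W V0 W' + I/tau); conditional on tau the
    coefficient posterior mean is the ridge-like closed form.
    """
    n, q = W.shape
    taus = np.logspace(-3, 3, grid_size)
    logw = np.empty(grid_size)
    means = np.empty((grid_size, q))
    V0 = np.diag(v0)
    for i, tau in enumerate(taus):
        cov = W @ V0 @ W.T + np.eye(n) / tau
        logw[i] = (
            stats.gamma.logpdf(tau, a0, scale=1.0 / b0)
            + stats.multivariate_normal.logpdf(y, W @ m0, cov)
            + np.log(tau)  # jacobian of the log-spaced grid
        )
        A = tau * W.T @ W + np.diag(1.0 / v0)
        means[i] = np.linalg.solve(A, tau * W.T @ y + m0 / v0)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return w @ means


def _mc_se(draws):
    """Batch-means Monte Carlo standard error (20 batches)."""
    nb = 20
    batches = draws[: len(draws) // nb * nb].reshape(nb, -1, *draws.shape[1:])
    return batches.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(nb)


class TestGibbs:
    def test_posterior_mean_matches_quadrature_oracle(self):
        """Gibbs coefficient means agree with the exact semi-conjugate
        posterior (quadrature over the precision) within 3 MC SEs on
        5 random small instances."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(40, 200))
            q = int(rng.integers(1, 5))
            X = rng.standard_normal((n, q))
            beta = rng.normal(0, 0.5, size=q)
            y = 0.3 + X @ beta + rng.normal(0, 0.6, size=n)
            sub = _sub(X, y)
            prior = _beliefs(sub.columns)
            draws, prec, names = gibbs_fit(sub, prior, McmcConfig(8000, 1000, seed))
            W = np.column_stack([np.ones(n), X])
            m0 = np.zeros(q + 1)
            v0 = np.full(q + 1, 100.0)
            exact = exact_posterior_mean(W, y, m0, v0, 2.5, 25.0)
            se = _mc_se(draws)
            assert np.all(np.abs(draws.mean(axis=0) - exact) < 3 * np.maximum(se, 1e-8))

    def test_known_precision_matches_ridge_formula(self):
        """With a near-degenerate precision belief the coefficient posterior
        is the analytic normal: mean (tau X'X + V0^-1)^-1 (tau X'y + V0^-1 m0)."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n, q = 150, 3
            X = rng.standard_normal((n, q))
            y = X @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 0.5, n)
            tau0 = 4.0
            prior = _beliefs([f"x{j+1}" for j in range(q)], var=2.0)
            prior.precision = PrecisionBelief(shape=1e8, rate=1e8 / tau0)
            sub = _sub(X, y)
            draws, _, _ = gibbs_fit(sub, prior, McmcConfig(6000, 1000, seed))
            W = np.column_stack([np.ones(n), X])
            A = tau0 * W.T @ W + np.eye(q + 1) / 2.0
            exact = np.linalg.solve(A, tau0 * W.T @ y)
            se = _mc_se(draws)
            assert np.all(np.abs(draws.mean(axis=0) - exact) < 4 * np.maximum(se, 1e-8))

    def test_degenerate_prior_pins_coefficient(self, rng):
        X = rng.standard_normal((200, 1))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.1, 200)
        sub = _sub(X, y)
        prior = _beliefs(["x1"])
        prior.coefficients["x1"] = CoefficientBelief(0.0, 1e-12)
        draws, _, names = gibbs_fit(sub, prior, McmcConfig(3000, 500, 0))
        slope = draws[:, names.index("x1")]
        assert abs(slope.mean()) < 1e-4

    def test_near_noiseless_matches_ols(self, rng):
        X = rng.standard_normal((500, 2))
        y = 1.0 + X @ np.array([0.5, -0.3]) + rng.normal(0, 1e-4, 500)
        sub = _sub(X, y)
        draws, _, _ = gibbs_fit(sub, _beliefs(sub.columns), McmcConfig(4000, 1000, 1))
        ols = ols_fit(X, y)
        se = _mc_se(draws)
        assert np.all(np.abs(draws.mean(axis=0) - ols) < 4 * np.maximum(se, 1e-6))

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((50, 2))
        y = X[:, 0] + rng.standard_normal(50)
        sub = _sub(X, y)
        d1, p1, _ = gibbs_fit(sub, _beliefs(sub.columns), McmcConfig(1000, 100, 7))
        d2, p2, _ = gibbs_fit(sub, _beliefs(sub.columns), McmcConfig(1000, 100, 7))
        assert np.array_equal(d1, d2) and np.array_equal(p1, p2)


class TestSummarize:
    def test_constant_draws_clamped_with_warning(self):
        draws = np.full((500, 2), 3.0)
        prec = np.abs(np.random.default_rng(0).normal(4, 0.5, 500))
        with pytest.warns(UserWarning, match="clamped"):
            coefs, _ = summarize_posterior(draws, prec, [INTERCEPT, "x1"])
        assert coefs["x1"].mean == 3.0
        assert coefs["x1"].variance == pytest.approx(1e-10)

    def test_gamma_moment_match_recovers_parameters(self, rng):
        prec = rng.gamma(2.5, 1.0 / 25.0, size=100_000)
        draws = rng.standard_normal((100_000, 1))
        _, belief = summarize_posterior(draws, prec, [INTERCEPT])
        assert belief.shape == pytest.approx(2.5, rel=0.1)
        assert belief.rate == pytest.approx(25.0, rel=0.1)

    def test_default_precision_prior_values(self):
        state = default_beliefs(["x1"])
        assert state.precision.shape == pytest.approx(2.5)
        assert state.precision.rate == pytest.approx(25.0)
        assert state.coefficients["x1"].variance == pytest.approx(100.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(np.zeros((50, 1)), np.ones(50), [INTERCEPT])


class TestSequentialUpdate:
    def test_untouched_coefficient_keeps_prior(self, rng):
        X = rng.standard_normal((30, 1))
        y = X[:, 0] + rng.standard_normal(30)
        frag = Fragmentation([_sub(X, y, ["x1"])], n_rows_total=30)
        init = default_beliefs(["x1", "x2"])
        state = dmu_fit(frag, init, McmcConfig(1000, 200, 0))
        assert state.coefficients["x2"].mean == 0.0
        assert state.coefficients["x2"].variance == 100.0
        assert state.coefficients["x1"].mean != 0.0

    def test_single_fragment_equals_direct_fit(self, rng):
        X = rng.standard_normal((100, 2))
        y = 0.5 * X[:, 0] + rng.standard_normal(100)
        sub = _sub(X, y)
        frag = Fragmentation([sub], n_rows_total=100)
        init = default_beliefs(sub.columns)
        chained = dmu_fit(frag, init, McmcConfig(2000, 400, 3))
        draws, prec, names = gibbs_fit(
            sub, init, McmcConfig(2000, 400, (3 + 7919) % (2**31 - 1))
        )
        coefs, precision = summarize_posterior(draws, prec, names)
        for c in names:
            assert chained.coefficients[c].mean == pytest.approx(coefs[c].mean)
        assert chained.precision.shape == pytest.approx(precision.shape)

    def test_disjoint_fragments_match_independent_fits(self, rng):
        X1 = rng.standard_normal((150, 1))
        y1 = 0.8 * X1[:, 0] + rng.normal(0, 0.3, 150)
        X2 = rng.standard_normal((150, 1))
        y2 = -0.4 * X2[:, 0] + rng.normal(0, 0.3, 150)
        subA = _sub(X1, y1, ["x1"])
        subB = _sub(X2, y2, ["x2"])
        init = default_beliefs(["x1", "x2"])
        frag = Fragmentation([subA, subB], n_rows_total=300)
        chained = dmu_fit(frag, init, McmcConfig(4000, 1000, 5), chain_precision=False)
        for sub, col, idx in ((subA, "x1", 1), (subB, "x2", 2)):
            solo_frag = Fragmentation([sub], n_rows_total=sub.s)
            solo = dmu_fit(solo_frag, init.copy(), McmcConfig(4000, 1000, 5), chain_precision=False)
            assert chained.coefficients[col].mean == pytest.approx(
                solo.coefficients[col].mean, abs=0.05
            )

    def test_history_and_key_conservation(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.standard_normal(40)
        frag = Fragmentation(
            [_sub(X, y), _sub(X + 1, y, ["x1", "x2"])], n_rows_total=80
        )
        init = default_beliefs(["x1", "x2", "x3"])
        state = dmu_fit(frag, init, McmcConfig(1000, 200, 0))
        assert set(state.coefficients) == {INTERCEPT, "x1", "x2", "x3"}
        assert len(state.history) == 2

    def test_empty_fragmentation_returns_init(self):
        init = default_beliefs(["x1"])
        with pytest.warns(UserWarning, match="unchanged"):
            state = dmu_fit(Fragmentation([], n_rows_total=5), init, McmcConfig(500, 100, 0))
        assert state.coefficients["x1"].mean == init.coefficients["x1"].mean


class TestPredict:
    def _state(self, means):
        cols = [c for c in means if c != INTERCEPT]
        state = default_beliefs(cols)
        for c, m in means.items():
            state.coefficients[c] = CoefficientBelief(m, 1.0)
        return state

    def test_zero_coefficients_predict_intercept(self, rng):
        test = TabularDataset(
            outcome=np.zeros(5), predictors=rng.standard_normal((5, 2))
        )
        state = self._state({INTERCEPT: 2.5, "x1": 0.0, "x2": 0.0})
        assert np.allclose(predict(state, test), 2.5)

    def test_true_model_plugin_is_noise_free(self, rng):
        X = rng.standard_normal((100, 3))
        y = 0.2 * X[:, 0] + 0.3 * X[:, 1] + 0.4 * X[:, 2]
        test = TabularDataset(outcome=y, predictors=X)
        state = self._state({INTERCEPT: 0.0, "x1": 0.2, "x2": 0.3, "x3": 0.4})
        assert np.mean((predict(state, test) - y) ** 2) < 1e-20

    def test_noiseless_single_fragment_fit_predicts_exactly(self, rng):
        X = rng.standard_normal((400, 2))
        y = 1.0 + 0.5 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(0, 1e-5, 400)
        frag = Fragmentation([_sub(X, y)], n_rows_total=400)
        state = dmu_fit(frag, default_beliefs(["x1", "x2"]), McmcConfig(4000, 1000, 2))
        test = TabularDataset(outcome=y[:50], predictors=X[:50])
        assert np.mean((predict(state, test) - y[:50]) ** 2) < 1e-4

    def test_incomplete_test_table_rejected(self, rng):
        pred = rng.standard_normal((4, 1))
        pred[0, 0] = np.nan
        test = TabularDataset(outcome=np.zeros(4), predictors=pred)
        with pytest.raises(ValueError, match="fully observed"):
            predict(self._state({INTERCEPT: 0.0, "x1": 1.0}), test)

    def test_schema_mismatch_rejected(self, rng):
        test = TabularDataset(
            outcome=np.zeros(3),
            predictors=rng.standard_normal((3, 1)),
            column_names=["other"],
        )
        with pytest.raises(ValueError, match="schema"):
            predict(self._state({INTERCEPT: 0.0, "x1": 1.0}), test)
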