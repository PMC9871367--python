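"""Screening, base-learners, single boosting steps, and full fits."""

import numpy as np
import pytest

from snpboost import (
    Batch,
    BoostState,
    Hyperparameters,
    compute_correlations,
    fit_l2boost_reference,
    fit_snpboost,
    screen_batch,
)
from snpboost.engine import (
    NO_OUTER,
    boosting_step,
    check_inner_stop,
    fit_base_learner,
)
from snpboost.losses import get_loss


def naive_pearson(x, u):
    x, u = np.asarray(x, float), np.asarray(u, float)
    xd, ud = x - x.mean(), u - u.mean()
    denom = np.sqrt((xd @ xd) * (ud @ ud))
    return 0.0 if denom == 0 else float((xd @ ud) / denom)


class TestComputeCorrelations:
    def test_self_correlation_is_one(self, rng):
        X = rng.normal(size=(30, 4))
        corr = compute_correlations(X, X[:, 2])
        assert corr[2] == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self, rng):
        X = np.column_stack([np.full(20, 1.5), rng.normal(size=20)])
        corr = compute_correlations(X, rng.normal(size=20))
        assert corr[0] == 0.0 and np.isfinite(corr).all()

    def test_constant_u_maps_to_zero(self, rng):
        corr = compute_correlations(rng.normal(size=(15, 3)), np.ones(15))
        np.testing.assert_array_equal(corr, 0.0)

    def test_matches_naive_per_column_oracle(self, rng):
        X = rng.normal(size=(30, 8))
        u = rng.normal(size=30)
        expected = [naive_pearson(X[:, j], u) for j in range(8)]
        np.testing.assert_allclose(compute_correlations(X, u), expected,
                                   atol=1e-12)

    def test_subset_selects_columns(self, rng):
        X = rng.normal(size=(25, 5))
        u = rng.normal(size=25)
        full = compute_correlations(X, u)
        np.testing.assert_allclose(compute_correlations(X, u, subset=[4, 1]),
                                   full[[4, 1]])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            compute_correlations(np.ones((1, 2)), np.ones(1))


class TestScreenBatch:
    def build(self, rng, target_abs_corr):
        """Columns with prescribed |correlation| to a fixed u (approximate)."""
        n = 400
        u = rng.normal(size=n)
        cols = []
        for c in target_abs_corr:
            noise = rng.normal(size=n)
            noise -= noise @ u / (u @ u) * u
            x = c * u / np.linalg.norm(u) + np.sqrt(1 - c ** 2) * noise / \
                np.linalg.norm(noise)
            cols.append(x)
        return np.column_stack(cols), u

    def test_brute_force_ranking(self, rng):
        X, u = self.build(rng, [0.9, 0.1, 0.5])
        batch = screen_batch(X, u, 2)
        abs_corr = np.abs(compute_correlations(X, u))
        top2 = set(np.argsort(-abs_corr)[:2])
        assert set(batch.indices) == top2 == {0, 2}
        assert batch.c_stop == pytest.approx(abs_corr[1])

    def test_whole_panel_batch_uses_sentinel(self, rng):
        X, u = self.build(rng, [0.3, 0.7])
        batch = screen_batch(X, u, 2)
        assert set(batch.indices) == {0, 1}
        assert batch.c_stop == NO_OUTER

    def test_exact_tie_breaks_to_lowest_index(self, rng):
        u = rng.normal(size=50)
        x = rng.normal(size=50)
        X = np.column_stack([x, x.copy()])  # identical correlations
        batch = screen_batch(X, u, 1)
        assert list(batch.indices) == [0]

    def test_all_zero_correlations_fall_back_to_first_variants(self, rng):
        X = np.tile(np.arange(4.0)[:, None], (1, 5))  # every column constant? no:
        X = np.ones((4, 5))                            # all constant -> corr 0
        batch = screen_batch(X, rng.normal(size=4), 3)
        assert list(batch.indices) == [0, 1, 2]
        assert batch.c_stop == 0.0


class TestFitBaseLearner:
    def test_exact_linear_relation(self):
        b0, slope, gamma = fit_base_learner([0.0, 1.0, 2.0], None, [0.0, 1.0, 2.0])
        assert (b0, slope) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))
        assert gamma.size == 0

    def test_two_point_line(self):
        b0, slope, _ = fit_base_learner([0.0, 2.0], None, [1.0, 3.0])
        assert b0 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_with_covariates(self, rng):
        n = 40
        x = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        u = rng.normal(size=n)
        D = np.column_stack([np.ones(n), x, C])
        expected = np.linalg.solve(D.T @ D, D.T @ u)
        b0, slope, gamma = fit_base_learner(x, C, u)
        np.testing.assert_allclose([b0, slope, *gamma], expected, atol=1e-8)

    def test_collinear_covariate_identified(self, rng):
        x = rng.normal(size=20)
        C = np.column_stack([x])  # duplicates the variant column
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_base_learner(x, C, rng.normal(size=20))


def make_state(y, n, q=0):
    loss = get_loss("l2")
    return BoostState(beta0=0.0, beta={}, gamma=np.zeros(q),
                      prediction=np.zeros(n),
                      u=loss.negative_gradient(y, np.zeros(n)), y=y)


class TestBoostingStep:
    def test_geometric_series_convergence_single_variant(self, rng):
        """With one variant, m steps at nu leave (1 - (1-nu)^m) of the OLS fit."""
        n, nu = 80, 0.1
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(scale=0.1, size=n)
        X = x[:, None]
        D = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.solve(D.T @ D, D.T @ y)

        state = make_state(y, n)
        batch = Batch(indices=np.array([0]), c_stop=NO_OUTER)
        for m in (1, 5, 20):
            while state.m < m:
                boosting_step(state, batch, X, None, nu, "l2")
            frac = 1 - (1 - nu) ** m
            assert state.beta[0] == pytest.approx(frac * beta_ols[1], rel=1e-9)
            assert state.beta0 == pytest.approx(frac * beta_ols[0], rel=1e-9)

    def test_full_learning_rate_reaches_ols_in_one_step(self, rng):
        n = 50
        x = rng.normal(size=n)
        y = 2.0 - x + rng.normal(scale=0.3, size=n)
        state = make_state(y, n)
        batch = Batch(indices=np.array([0]), c_stop=NO_OUTER)
        boosting_step(state, batch, x[:, None], None, 1.0, "l2")
        # residuals orthogonal to the design after a full step
        assert abs(state.u.sum()) < 1e-8
        assert abs(state.u @ x) < 1e-8

    def test_training_loss_never_increases_under_l2(self, rng):
        n, p = 60, 10
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = X[:, 0] - X[:, 3] + rng.normal(size=n)
        state = make_state(y, n)
        loss = get_loss("l2")
        prev = loss.evaluate(y, state.prediction)
        batch = screen_batch(X, state.u, p)
        for _ in range(40):
            boosting_step(state, batch, X, None, 0.1, "l2")
            cur = loss.evaluate(y, state.prediction)
            assert cur <= prev + 1e-12
            prev = cur

    def test_prediction_reconstructable_from_coefficients(self, rng):
        n, p, q = 50, 8, 2
        X = rng.normal(size=(n, p))
        C = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        state = BoostState(beta0=0.0, beta={}, gamma=np.zeros(q),
                           prediction=np.zeros(n),
                           u=y.copy(), y=y)
        batch = screen_batch(X, state.u, 5)
        for _ in range(25):
            boosting_step(state, batch, X, C, 0.1, "l2")
        rebuilt = state.beta0 + C @ state.gamma
        for j, b in state.beta.items():
            rebuilt = rebuilt + b * X[:, j]
        np.testing.assert_allclose(rebuilt, state.prediction, atol=1e-8)


class TestCheckInnerStop:
    def test_sentinel_never_fires_on_correlations(self, rng):
        X = rng.normal(size=(30, 3))
        state = make_state(rng.normal(size=30), 30)
        batch = Batch(indices=np.arange(3), c_stop=NO_OUTER)
        assert not check_inner_stop(state, batch, X)

    def test_direct_inequality(self, rng):
        X = rng.normal(size=(40, 2))
        state = make_state(rng.normal(size=40), 40)
        uc = state.u - state.u.mean()
        u_norm = float(np.sqrt(uc @ uc))  # scales coincide at batch creation
        in_batch_max = np.abs(compute_correlations(X, state.u)).max()
        assert check_inner_stop(
            state, Batch(np.arange(2), in_batch_max + 0.1, u_norm), X)
        assert not check_inner_stop(state, Batch(np.arange(2), 0.0, u_norm), X)

    def test_m_batch_budget_fires(self, rng):
        X = rng.normal(size=(30, 3))
        state = make_state(rng.normal(size=30), 30)
        state.steps_in_batch = 5
        batch = Batch(indices=np.arange(3), c_stop=NO_OUTER)
        assert check_inner_stop(state, batch, X, m_batch=5)
        assert not check_inner_stop(state, batch, X, m_batch=6)


def orthogonal_design(rng, n, p):
    """Columns mutually orthogonal and orthogonal to the intercept."""
    raw = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    q, _ = np.linalg.qr(raw)
    return q[:, 1:] * np.sqrt(n)


class TestFullFits:
    def test_reference_with_zero_iterations_is_null_model(self, rng):
        model, path = fit_l2boost_reference(rng.normal(size=(20, 3)),
                                            rng.normal(size=20), m_stop=0)
        assert model.intercept == 0.0 and model.n_variants == 0
        assert path.iterations == []

    def test_reference_converges_to_ols(self, rng):
        n, p = 120, 4
        X = rng.normal(size=(n, p))
        y = X @ np.array([1.0, -0.5, 0.0, 2.0]) + rng.normal(scale=0.5, size=n)
        model, _ = fit_l2boost_reference(X, y, m_stop=20000, nu=0.1)
        D = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        fitted = np.array([model.coefficients.get(f"v{j + 1:04d}", 0.0)
                           for j in range(p)])
        np.testing.assert_allclose(fitted, ols[1:], atol=1e-3)
        assert model.intercept == pytest.approx(ols[0], abs=1e-3)

    def test_batched_fit_reduces_to_reference(self, rng):
        n, p, m = 150, 30, 120
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = X[:, 4] - 0.5 * X[:, 9] + rng.normal(size=n)
        X_val = rng.binomial(2, 0.3, size=(40, p)).astype(float)
        y_val = rng.normal(size=40)
        ref_model, ref_path = fit_l2boost_reference(X, y, m_stop=m)
        hp = Hyperparameters(p_batch=p, m_batch=m, b_max=1, b_stop=1)
        bat_model, bat_path = fit_snpboost(X, y, X_val, y_val, hp)
        assert bat_path.selected_sequence() == ref_path.selected_sequence()
        for (ma, ja, inca), (mb, jb, incb) in zip(bat_path.iterations,
                                                  ref_path.iterations):
            assert (ma, ja) == (mb, jb)
            assert inca == pytest.approx(incb, abs=1e-10)

    def test_orthogonal_selection_order_matches_reference(self, rng):
        n, p, m = 128, 24, 60
        X = orthogonal_design(rng, n, p)
        y = X[:, [1, 7, 13]] @ np.array([1.0, -0.8, 0.5]) + \
            rng.normal(scale=0.5, size=n)
        _, ref_path = fit_l2boost_reference(X, y, m_stop=m)
        for p_batch in (4, 12):
            hp = Hyperparameters(p_batch=p_batch, m_batch=m, b_max=500,
                                 b_stop=10 ** 6, m_total=m)
            _, path = fit_snpboost(X, y, X[:32], y[:32], hp)
            assert path.selected_sequence() == ref_path.selected_sequence()

    def test_deterministic_fit_paths(self, small_sim):
        from snpboost import simulate_phenotype
        cfg, G = small_sim
        pheno, _ = simulate_phenotype(G, cfg)
        X, y = G.dosages, pheno.y
        hp = Hyperparameters(p_batch=10)
        paths = [fit_snpboost(X[:180], y[:180], X[180:], y[180:], hp)[1]
                 for _ in range(2)]
        assert paths[0].iterations == paths[1].iterations
        assert paths[0].batches == paths[1].batches

    def test_sparsity_bounded_by_iterations(self, small_sim):
        from snpboost import simulate_phenotype
        cfg, G = small_sim
        pheno, _ = simulate_phenotype(G, cfg)
        X, y = G.dosages, pheno.y
        hp = Hyperparameters(p_batch=8)
        model, path = fit_snpboost(X[:180], y[:180], X[180:], y[180:], hp)
        assert model.n_variants <= model.n_iterations
        assert model.n_variants <= len(path.batches) * 8

    def test_empty_validation_set_refused(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="iteration budget"):
            fit_snpboost(X, rng.normal(size=20), X[:0], np.array([]),
                         Hyperparameters(p_batch=3))

    def test_log_loss_requires_binary_phenotype(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="0,1"):
            fit_snpboost(X, y, X, y, Hyperparameters(p_batch=3, loss="log"))

    def test_log_loss_training_loss_decreases(self, rng):
        n, p = 200, 15
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        eta = 1.2 * (X[:, 2] - X[:, 2].mean())
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        hp = Hyperparameters(p_batch=5, loss="log", b_stop=2)
        model, path = fit_snpboost(X[:150], y[:150], X[150:], y[150:], hp)
        assert model.loss == "log"
        assert model.n_variants >= 1
        # recorded validation losses are finite and the fit made progress
        losses = [rec["val_loss"] for rec in path.batches]
        assert all(np.isfinite(losses))

    def test_learning_rate_halving_consistency(self, rng):
        """Half nu, double steps: predictions agree up to o(nu) on one variant."""
        n = 100
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(scale=0.2, size=n)
        X = x[:, None]
        batch = Batch(indices=np.array([0]), c_stop=NO_OUTER)

        def run(nu, steps):
            state = make_state(y, n)
            for _ in range(steps):
                boosting_step(state, batch, X, None, nu, "l2")
            return state.prediction

        diff = np.max(np.abs(run(0.1, 10) - run(0.05, 20)))
        coarse = np.max(np.abs(run(0.1, 10) - run(0.2, 5)))
        assert diff < coarse  # refinement shrinks the discrepancy
        assert diff < 0.05 * np.max(np.abs(run(0.1, 10)))
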