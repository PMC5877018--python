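import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lars_path

from scalesel.data_model import standardize_full
from scalesel.ss_select import (
    SSConfig,
    SingularDesignError,
    choose_min_aic,
    eligible_columns,
    final_model,
    ols_aic,
    ss_forward_stagewise,
    ss_forward_stepwise,
    ss_lars,
    ss_lasso,
)
from scalesel.synthetic import SyntheticScenario, scenario_design, simulate_study

from conftest import make_design, standardized_random_design


def std_cols(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def std_vec(y):
    return (y - y.mean()) / y.std(ddof=1)


def multiscale_design(rng, n=300, n_concepts=4, rho=0.9):
    """Concepts observed at two 'scales' as rho-correlated column pairs."""
    names, concepts, scales, cols = [], [], [], []
    for c in range(n_concepts):
        u = rng.standard_normal(n)
        v = rho * u + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        for scale, x in (("CBG", u), ("CT", v)):
            names.append(f"c{c}_{scale}")
            concepts.append(f"c{c}")
            scales.append(scale)
            cols.append(x)
    X = std_cols(np.column_stack(cols))
    return make_design(X, names, concepts, scales)


class TestOlsAic:
    def test_formula_value(self):
        assert ols_aic(100.0, 100, 0) == pytest.approx(2.0)

    def test_useless_parameter_costs_two(self):
        assert ols_aic(50.0, 80, 3) - ols_aic(50.0, 80, 2) == pytest.approx(2.0)

    def test_zero_rss_warns_and_returns_neg_inf(self):
        with pytest.warns(RuntimeWarning):
            assert ols_aic(0.0, 10, 1) == float("-inf")

    def test_constant_offset_from_statsmodels(self, rng):
        """Our AIC differs from the reference library's Gaussian AIC by an
        additive constant independent of the number of regressors."""
        n = 150
        X = rng.standard_normal((n, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(n)
        offsets = []
        for k in (1, 3, 6):
            res = sm.OLS(y, X[:, :k]).fit()
            offsets.append(res.aic - ols_aic(res.ssr, n, k))
        assert np.ptp(offsets) < 1e-8


class TestEligibility:
    def test_active_sibling_blocks_other_scales(self, rng):
        design = multiscale_design(rng, n=50, n_concepts=2)
        elig = eligible_columns(design, {"c0_CT"})
        assert "c0_CBG" not in elig and "c0_CT" not in elig
        assert {"c1_CBG", "c1_CT"} <= set(elig)

    def test_empty_active_set_everything_eligible(self, rng):
        design = multiscale_design(rng, n=50, n_concepts=3)
        assert len(eligible_columns(design, set())) == design.p

    def test_overlapping_active_excluded_raises(self, rng):
        design = multiscale_design(rng, n=50, n_concepts=2)
        with pytest.raises(ValueError):
            eligible_columns(design, {"c0_CT"}, {"c0_CT"})


class TestForwardStepwise:
    def test_recovers_single_true_predictor_then_stops(self, rng):
        n = 200
        design = standardized_random_design(rng, n, 5)
        y = std_vec(2.0 * design.X["x1"].to_numpy())
        # oracle: exhaustive OLS over single candidates
        aics = {
            name: ols_aic(
                float(np.sum((y - design.X[name] * (design.X[name] @ y) / (n - 1)) ** 2)),
                n,
                1,
            )
            for name in design.X.columns
        }
        assert min(aics, key=aics.get) == "x1"
        path = ss_forward_stepwise(design, y)
        assert path.steps[0].column == "x1"
        assert len(path.steps) == 1  # no second candidate improves by epsilon

    def test_identical_siblings_only_one_enters(self, rng):
        n = 150
        x = std_vec(rng.standard_normal(n))
        noise = std_cols(rng.standard_normal((n, 2)))
        X = np.column_stack([x, x, noise])
        design = make_design(
            X, ["dup_CBG", "dup_CT", "z0", "z1"],
            ["dup", "dup", "z0", "z1"], ["CBG", "CT", "CT", "CT"],
        )
        y = std_vec(x + 0.1 * rng.standard_normal(n))
        path = ss_forward_stepwise(design, y)
        active = path.terminal.active
        assert ("dup_CBG" in active) != ("dup_CT" in active)
        # tie on identical columns broken by the smaller variable number
        assert "dup_CBG" in active

    def test_infinite_epsilon_gives_empty_model(self, rng):
        design = standardized_random_design(rng, 100, 4)
        y = std_vec(design.X["x0"].to_numpy() + 0.1 * rng.standard_normal(100))
        path = ss_forward_stepwise(design, y, SSConfig(epsilon=np.inf))
        assert len(path.steps) == 0


class TestForwardStagewise:
    def test_all_correlations_below_tolerance_empty_path(self, rng):
        design = standardized_random_design(rng, 500, 4)
        X = design.values()
        y = std_vec(rng.standard_normal(500))
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]  # orthogonal to all x
        path = ss_forward_stagewise(design, std_vec(y))
        assert path.terminal.coef == {}

    def test_single_predictor_matches_naive_iteration(self, rng):
        """Independent oracle: re-run the increments with a plain residual
        vector, no Gram shortcuts."""
        n = 400
        design = standardized_random_design(rng, n, 1)
        x = design.values()[:, 0]
        y = std_vec(0.8 * x + 0.3 * rng.standard_normal(n))
        cfg = SSConfig(step_size=0.001, tolerance=0.01)
        r = y.copy()
        beta = 0.0
        for _ in range(100_000):
            c = (x @ r) / np.sqrt((x @ x) * (r @ r))
            if abs(c) < cfg.tolerance:
                break
            beta += cfg.step_size * np.sign(c)
            r -= cfg.step_size * np.sign(c) * x
        path = ss_forward_stagewise(design, y, cfg)
        assert path.terminal.coef["x0"] == pytest.approx(beta, abs=1e-9)
        # terminal coefficient sits within a step of the tolerance-soft limit
        ols = (x @ y) / (x @ x)
        soft = ols - cfg.tolerance * np.sqrt((r @ r) / (x @ x))
        assert abs(path.terminal.coef["x0"] - soft) < 5 * cfg.step_size

    def test_more_correlated_sibling_wins(self, rng):
        n = 2000
        u = rng.standard_normal(n)
        a = std_vec(0.995 * u + np.sqrt(1 - 0.995**2) * rng.standard_normal(n))
        b = std_vec(0.93 * u + np.sqrt(1 - 0.93**2) * rng.standard_normal(n))
        design = make_design(
            np.column_stack([std_cols(a[:, None]), std_cols(b[:, None])]),
            ["c_CBG", "c_CT"], ["c", "c"], ["CBG", "CT"],
        )
        y = std_vec(u)
        path = ss_forward_stagewise(design, y)
        touched = {s.column for s in path.steps if s.column}
        assert touched <= {"c_CBG"}

    def test_max_steps_truncation_flag(self, rng):
        design = standardized_random_design(rng, 200, 3)
        y = std_vec(design.X["x0"] + design.X["x1"])
        path = ss_forward_stagewise(design, y, SSConfig(max_steps=5))
        assert path.truncated


class TestLarsAndLasso:
    @pytest.mark.parametrize("method,fn", [("lar", ss_lars), ("lasso", ss_lasso)])
    def test_single_scale_matches_textbook_path(self, rng, method, fn):
        """With one scale per concept the constraint never binds and every
        knot must reproduce the unconstrained reference path."""
        for _ in range(5):
            n, p = int(rng.integers(60, 250)), int(rng.integers(4, 10))
            design = standardized_random_design(rng, n, p)
            X = design.values()
            beta = rng.standard_normal(p) * (rng.random(p) < 0.5)
            y = std_vec(X @ beta + rng.standard_normal(n))
            _, _, ref = lars_path(X, y, method=method)
            path = fn(design, y)
            assert ref.shape[1] - 1 == len(path.steps)
            for i, step in enumerate(path.steps):
                got = np.array([step.coef.get(f"x{j}", 0.0) for j in range(p)])
                np.testing.assert_allclose(got, ref[:, i + 1], atol=1e-8)

    def test_single_column_full_ols_in_one_knot(self, rng):
        design = standardized_random_design(rng, 100, 1)
        x = design.values()[:, 0]
        y = std_vec(0.5 * x + rng.standard_normal(100))
        path = ss_lars(design, y)
        assert len(path.steps) == 1
        assert path.terminal.coef["x0"] == pytest.approx((x @ y) / (x @ x), abs=1e-10)

    def test_constraint_keeps_sibling_out(self, rng):
        design = multiscale_design(rng, n=600, n_concepts=2, rho=0.95)
        y = std_vec(
            0.6 * design.X["c0_CT"].to_numpy()
            + 0.3 * design.X["c1_CBG"].to_numpy()
            + 0.4 * rng.standard_normal(600)
        )
        for fn in (ss_lars, ss_lasso):
            path = fn(design, y)
            active = set(path.terminal.active)
            assert "c0_CT" in active and "c0_CBG" not in active
            for step in path.steps:
                concepts = [design.info(a).concept for a in step.active]
                assert len(concepts) == len(set(concepts))

    def test_lasso_orthonormal_soft_threshold(self, rng):
        """On an orthogonal design the lasso knots are soft-thresholded OLS
        coefficients."""
        n, p = 64, 5
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))  # exactly orthonormal
        design = make_design(Q)
        theta = np.array([2.0, -1.5, 1.0, 0.5, 0.0])
        y = Q @ theta + 0.01 * rng.standard_normal(n)
        path = ss_lasso(design, y)
        # at each knot the active coefficients are OLS soft-thresholded at
        # the largest still-inactive |inner product|
        inner = Q.T @ y
        order = np.argsort(-np.abs(inner))
        for i, step in enumerate(path.steps[:-1]):
            lam = abs(inner[order[i + 1]])
            expect = np.sign(inner) * np.maximum(np.abs(inner) - lam, 0.0)
            got = np.array([step.coef.get(f"x{j}", 0.0) for j in range(p)])
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_lasso_equals_lars_without_drops(self, rng):
        design = standardized_random_design(rng, 200, 6)
        X = design.values()
        y = std_vec(X @ np.array([1.0, 0.8, 0.6, 0.0, 0.0, 0.0]) + 0.3 * rng.standard_normal(200))
        lars = ss_lars(design, y)
        lasso = ss_lasso(design, y)
        if all(s.event != "drop" for s in lasso.steps):
            assert len(lars.steps) == len(lasso.steps)
            for a, b in zip(lars.steps, lasso.steps):
                assert a.active == b.active
                for k in a.coef:
                    assert a.coef[k] == pytest.approx(b.coef[k], abs=1e-10)

    def test_lasso_agrees_with_coordinate_descent_oracle(self, rng):
        """Knot coefficients match an independently-fitted penalized
        regression at the knot's penalty level."""
        for _ in range(5):
            n, p = 120, 6
            design = standardized_random_design(rng, n, p)
            X = design.values()
            y = std_vec(X @ (rng.standard_normal(p) * (rng.random(p) < 0.7))
                        + 0.5 * rng.standard_normal(n))
            path = ss_lasso(design, y)
            for step in path.steps:
                resid = y - X @ np.array([step.coef.get(f"x{j}", 0.0) for j in range(p)])
                lam = np.max(np.abs(X.T @ resid))  # KKT: common active |inner|
                if lam < 1e-10:
                    continue
                oracle = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-12,
                               max_iter=200_000).fit(X, y)
                got = np.array([step.coef.get(f"x{j}", 0.0) for j in range(p)])
                np.testing.assert_allclose(got, oracle.coef_, atol=1e-6)

    def test_kkt_at_every_lasso_knot(self, rng):
        design = standardized_random_design(rng, 150, 8)
        X = design.values()
        y = std_vec(X @ (rng.standard_normal(8) * (rng.random(8) < 0.6))
                    + 0.4 * rng.standard_normal(150))
        path = ss_lasso(design, y)
        for step in path.steps:
            beta = np.array([step.coef.get(f"x{j}", 0.0) for j in range(8)])
            corr = X.T @ (y - X @ beta)
            active = [j for j in range(8) if f"x{j}" in step.active]
            inactive = [j for j in range(8) if j not in active]
            if not active:
                continue
            cmax = np.abs(corr[active])
            assert np.ptp(cmax) < 1e-6  # active share one |correlation|
            if inactive:
                assert np.max(np.abs(corr[inactive])) <= cmax.max() + 1e-8

    def test_rank_deficient_candidate_raises_in_stepwise(self, rng):
        # duplicated column under two different concepts: once one is
        # active, trying the other gives a singular trial fit
        x = std_vec(rng.standard_normal(50))
        z = std_vec(rng.standard_normal(50))
        design = make_design(np.column_stack([x, x, z]), ["a", "b", "z"], ["a", "b", "z"])
        y = std_vec(x + 0.5 * z + 0.01 * rng.standard_normal(50))
        with pytest.raises(SingularDesignError):
            ss_forward_stepwise(design, y)


class TestChooseMinAic:
    def test_single_knot(self, rng):
        design = standardized_random_design(rng, 80, 1)
        y = std_vec(design.X["x0"] + 0.5 * rng.standard_normal(80))
        path = ss_lars(design, y)
        model = choose_min_aic(path, design, y)
        assert model.step_index == 0

    def test_noise_knot_skipped(self, rng):
        n = 300
        design = standardized_random_design(rng, n, 6)
        X = design.values()
        y = std_vec(X[:, 0] * 1.0 + X[:, 1] * 0.5 + 0.5 * rng.standard_normal(n))
        path = ss_lars(design, y)
        model = choose_min_aic(path, design, y)
        aics = [s.aic for s in path.steps]
        assert model.aic == min(aics)
        assert model.step_index == int(np.argmin(aics))

    def test_terminal_chosen_when_aic_monotone(self, rng):
        n = 500
        design = standardized_random_design(rng, n, 3)
        X = design.values()
        y = std_vec(X @ np.array([1.0, 0.7, 0.5]) + 0.2 * rng.standard_normal(n))
        path = ss_lars(design, y)
        model = choose_min_aic(path, design, y)
        assert model.step_index == len(path.steps) - 1


class TestOneScaleInvariant:
    @pytest.mark.parametrize("seed", range(6))
    def test_no_model_contains_two_scales_of_one_concept(self, seed):
        sc = SyntheticScenario(
            n_ct=8, cbgs_per_ct=2, cbks_per_cbg=2, n_total=400, seed=seed,
            n_underweight=0, n_race_excluded=0, n_missing=0,
            sigma_eps=0.8,
            area_concepts={"A": ("CBG", "CT"), "B": ("CBG", "CT"), "C": ("CBK", "CBG", "CT")},
            effects={"A": ("CT", 0.3), "C": ("CBG", 0.25), "VisitAge": ("individual", 0.2)},
        )
        geo, tables, cohort, _, _ = simulate_study(sc)
        design = scenario_design(sc, cohort, tables)
        Xs, ys, _ = standardize_full(design, cohort["BMIZ"].to_numpy())
        for fn in (ss_forward_stepwise, ss_forward_stagewise, ss_lars, ss_lasso):
            path = fn(Xs, ys)
            for step in path.steps:
                concepts = [design.info(a).concept for a in step.active]
                assert len(concepts) == len(set(concepts)), (fn.__name__, step.active)
            model = final_model(path, Xs, ys)
            concepts = [design.info(a).concept for a in model.active]
            assert len(concepts) == len(set(concepts))
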