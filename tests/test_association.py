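"""LASSO screen, per-assay OLS, empirical-Bayes moderation, BH adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnoprot import NPXMatrix
from somnoprot.association import (
    AssayFit,
    bh_adjust,
    estimate_prior,
    fit_assay,
    lasso_coordinate_descent,
    lasso_objective,
    lasso_path,
    lasso_screen,
    moderate,
    prepare_design,
    run_association,
    squeeze_variance,
)


@pytest.fixture(scope="module")
def cohort_design(cohort_study):
    return prepare_design(cohort_study.phenotypes, cohort_study.cohort, "secondary")


class TestPrepareDesign:
    def test_linear_design_has_ten_columns(self, cohort_design):
        assert cohort_design.shape == (77, 10)
        assert list(cohort_design.columns[:2]) == ["intercept", "sleep_z"]

    def test_quadratic_flag_adds_centered_square(self, cohort_study):
        d = prepare_design(cohort_study.phenotypes, cohort_study.cohort,
                           "secondary", quadratic=True)
        assert d.shape[1] == 11
        sq = d["sleep_z_sq"].to_numpy()
        assert abs(sq.mean()) < 1e-12
        np.testing.assert_allclose(
            sq, d["sleep_z"].to_numpy() ** 2 - (d["sleep_z"] ** 2).mean()
        )

    def test_missing_participant_rejected(self, cohort_study):
        with pytest.raises(ValueError, match="missing participants"):
            prepare_design(cohort_study.phenotypes,
                           cohort_study.cohort.iloc[:-1], "secondary")

    def test_collinear_columns_named(self, cohort_study):
        cov = cohort_study.cohort.copy()
        cov["bmi"] = 2.0 * cov["age"]  # force rank deficiency
        with pytest.raises(ValueError, match="collinear"):
            prepare_design(cohort_study.phenotypes, cov, "secondary")

    def test_sleep_outcome_standardized(self, cohort_design):
        z = cohort_design["sleep_z"].to_numpy()
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestLassoSolver:
    def test_lambda_at_or_above_lambda_max_kills_everything(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        lam_max = np.abs(X.T @ y).max() / len(y)
        beta = lasso_coordinate_descent(X, y, lam_max * 1.0001)
        assert np.all(beta == 0.0)

    def test_single_orthonormal_predictor_soft_threshold(self):
        # x scaled so x'x/n = 1 and OLS slope 2.0; S(2.0, 0.5) = 1.5
        n = 50
        x = np.ones(n)
        x[: n // 2] = -1.0
        y = 2.0 * x
        beta = lasso_coordinate_descent(x[:, None], y, 0.5)
        assert beta[0] == pytest.approx(1.5, abs=1e-10)

    def test_orthonormal_design_matches_soft_threshold_closed_form(self):
        rng = np.random.default_rng(3)
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)  # columns orthonormal in the 1/n inner product
        b_true = rng.normal(0, 2, p)
        y = X @ b_true + rng.standard_normal(n) * 0.1
        lam = 0.7
        ols = X.T @ y / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        beta = lasso_coordinate_descent(X, y, lam)
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_objective_non_increasing_in_sweeps(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 12))
        y = X[:, 0] * 2 + rng.standard_normal(30)
        lam = 0.1
        pen = np.ones(12)
        objs = [
            lasso_objective(X, y, lasso_coordinate_descent(
                X, y, lam, max_sweeps=k), lam, pen)
            for k in range(1, 8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_matches_sklearn_on_all_penalized_problem(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 30))
        y = X[:, :4] @ np.array([1.5, -1.0, 0.6, 0.3]) + rng.standard_normal(60)
        for lam in (0.02, 0.1, 0.4):
            mine = lasso_coordinate_descent(X, y, lam)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                        max_iter=100000).fit(X, y).coef_
            np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_unpenalized_columns_satisfy_ols_stationarity(self):
        # KKT: zero gradient on unpenalized columns, |grad| <= lam elsewhere
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 10))
        y = X[:, 0] - X[:, 5] + rng.standard_normal(50)
        penalty = np.ones(10)
        penalty[:3] = 0.0
        lam = 0.15
        beta = lasso_coordinate_descent(X, y, lam, penalty)
        grad = X.T @ (y - X @ beta) / len(y)
        assert np.max(np.abs(grad[:3])) < 1e-7
        assert np.all(np.abs(grad[3:]) <= lam + 1e-7)

    def test_path_requires_decreasing_grid(self):
        X = np.eye(4)
        y = np.ones(4)
        with pytest.raises(ValueError, match="non-increasing"):
            lasso_path(X, y, [0.1, 0.5])

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            lasso_coordinate_descent(np.eye(3), np.ones(3), -0.1)


class TestLassoScreen:
    def test_screen_recovers_planted_assays(self, cohort_study, cohort_npx,
                                            cohort_design):
        selected, info = lasso_screen(cohort_npx, cohort_design, seed=1)
        truth = set(cohort_study.truth.signal_assay_ids)
        assert len(truth & set(selected)) >= 8
        assert info["n_selected"] == len(selected)

    def test_screen_is_seed_deterministic(self, cohort_npx, cohort_design):
        s1, _ = lasso_screen(cohort_npx, cohort_design, seed=7)
        s2, _ = lasso_screen(cohort_npx, cohort_design, seed=7)
        assert s1 == s2

    def test_pure_noise_selects_nothing_or_near_nothing(self):
        rng = np.random.default_rng(21)
        n, p = 60, 120
        idx = [f"P{i:03d}" for i in range(n)]
        cols = [f"A{j}" for j in range(p)]
        npx = NPXMatrix(
            pd.DataFrame(rng.standard_normal((n, p)), index=idx, columns=cols),
            pd.DataFrame({"panel": "CVD-II", "protein_id": cols},
                         index=pd.Index(cols)),
        )
        design = pd.DataFrame({"intercept": np.ones(n),
                               "sleep_z": rng.standard_normal(n)}, index=idx)
        selected, _ = lasso_screen(npx, design, seed=2)
        assert len(selected) <= 5


class TestFitAssay:
    def _design(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"intercept": np.ones(n), "sleep_z": rng.standard_normal(n),
             "age": rng.normal(87, 4, n)},
            index=[f"P{i}" for i in range(n)],
        )

    def test_noise_free_linear_response_recovered_exactly(self):
        d = self._design(20)
        y = pd.Series(1.0 + 0.8 * d["sleep_z"] - 0.02 * d["age"], index=d.index)
        fit = fit_assay(y, d, assay_id="A", term="sleep_z")
        assert fit.beta == pytest.approx(0.8, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_on_worked_fixture(self):
        d = self._design(12, seed=3)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.standard_normal(12), index=d.index)
        fit = fit_assay(y, d, assay_id="A", term="sleep_z")
        X = d.to_numpy()
        beta_all = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        resid = y.to_numpy() - X @ beta_all
        sigma2 = resid @ resid / (12 - 3)
        assert fit.beta == pytest.approx(beta_all[1], abs=1e-10)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-10)
        assert fit.df_resid == 9

    def test_missing_rows_excluded(self):
        d = self._design(20)
        y = pd.Series(0.5 * d["sleep_z"], index=d.index)
        y.iloc[:5] = np.nan
        fit = fit_assay(y, d, assay_id="A")
        assert fit.n_used == 15
        assert fit.df_resid == 12

    def test_too_few_rows_unusable(self):
        d = self._design(12)
        y = pd.Series(np.nan, index=d.index)
        y.iloc[:4] = 1.0
        assert fit_assay(y, d, assay_id="A") is None


class TestModeration:
    # oracle values computed once with Bioconductor limma::squeezeVar
    # (see the 12-assay fixture): equal and heterogeneous residual dfs
    S2 = np.array([0.52, 1.31, 0.87, 2.10, 0.66, 1.05, 0.44, 1.77, 0.93,
                   1.22, 0.71, 1.58])

    def test_prior_matches_limma_equal_dfs(self):
        d0, s0 = estimate_prior(self.S2, np.full(12, 67))
        assert d0 == pytest.approx(10.6086865146, rel=1e-9)
        assert s0 == pytest.approx(0.909122436066, rel=1e-9)
        post = squeeze_variance(self.S2, np.full(12, 67), d0, s0)
        assert post[0] == pytest.approx(0.573190926498, rel=1e-9)
        assert post[3] == pytest.approx(1.93721349606, rel=1e-9)

    def test_prior_matches_limma_heterogeneous_dfs(self):
        df = np.array([10, 20, 30, 15, 25, 12, 18, 22, 28, 14, 16, 24])
        d0, s0 = estimate_prior(self.S2, df)
        assert d0 == pytest.approx(18.8051584645, rel=1e-9)
        assert s0 == pytest.approx(0.991210164253, rel=1e-9)
        post = squeeze_variance(self.S2, df, d0, s0)
        assert post[0] == pytest.approx(0.827624824206, rel=1e-9)
        assert post[-1] == pytest.approx(1.32133290097, rel=1e-9)

    def test_shrinkage_limits_and_worked_value(self):
        s2 = np.array([3.0])
        df = np.array([4])
        assert squeeze_variance(s2, df, 0.0, 1.0)[0] == 3.0  # no shrinkage
        assert squeeze_variance(s2, df, np.inf, 1.0)[0] == 1.0  # full collapse
        assert squeeze_variance(s2, df, 4.0, 1.0)[0] == 2.0  # (4*1+4*3)/8

    def test_moderate_infinite_d0_on_homogeneous_variances(self):
        rng = np.random.default_rng(0)
        # variances clustered tightly -> observed spread below sampling floor
        fits = [AssayFit(f"A{i}", rng.normal(0, 0.1), 0.12,
                         float(np.exp(rng.normal(0, 0.01))), 60, 70)
                for i in range(40)]
        state = moderate(fits)
        assert np.isinf(state.d0)
        assert np.allclose(state.s_tilde_sq, state.s0_sq)

    def test_moderate_requires_two_fits(self):
        with pytest.raises(ValueError, match="at least two"):
            moderate([AssayFit("A", 1.0, 0.1, 1.0, 10, 13)])

    def test_all_zero_variances_rejected(self):
        fits = [AssayFit("A", 1.0, 0.1, 0.0, 10, 13),
                AssayFit("B", 1.0, 0.1, 0.0, 10, 13)]
        with pytest.raises(ValueError, match="zero"):
            moderate(fits)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.random(rng.integers(1, 40))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestRunAssociation:
    def test_planted_positive_effect_reported_up(self, cohort_study, cohort_npx):
        results, info = run_association(
            cohort_npx, cohort_study.phenotypes, cohort_study.cohort,
            "secondary", seed=1,
        )
        truth = cohort_study.truth.true_betas
        found = {r.assay_id: r for r in results if r.assay_id in truth}
        assert len(found) >= 8
        for aid, r in found.items():
            assert r.direction == ("up" if truth[aid] > 0 else "down")
            assert r.beta_sleep == pytest.approx(truth[aid], abs=0.5)
        assert results == sorted(results, key=lambda r: (r.p, r.assay_id))

    def test_empty_selection_is_a_valid_outcome(self):
        # constant assay columns cannot enter the screen: deterministic
        # empty shortlist, warned about, with an empty (valid) result
        rng = np.random.default_rng(31)
        n, p = 60, 8
        idx = [f"P{i:03d}" for i in range(n)]
        cols = [f"A{j}" for j in range(p)]
        npx = NPXMatrix(
            pd.DataFrame(np.ones((n, p)), index=idx, columns=cols),
            pd.DataFrame({"panel": "CVD-II", "protein_id": cols},
                         index=pd.Index(cols)),
        )
        phen = pd.DataFrame(
            {"avg_secondary_tst": rng.gamma(1.0, 6.0, n) * (rng.random(n) < 0.5),
             "avg_daytime_tst": 0.0, "avg_afternoon_tst": 0.0},
            index=pd.Index(idx, name="participant_id"),
        )
        cov = pd.DataFrame(
            {"age": rng.normal(87, 4, n), "sex": rng.integers(0, 2, n),
             "bmi": rng.normal(22, 3, n), "avg_steps": rng.normal(5000, 2000, n),
             "metabolic_disease": rng.integers(0, 2, n),
             "hypertension": rng.integers(0, 2, n),
             "arrhythmia_hf": rng.integers(0, 2, n),
             "cystatin_c": rng.normal(1.2, 0.3, n)},
            index=pd.Index(idx, name="participant_id"),
        )
        with pytest.warns(UserWarning, match="no assays"):
            results, info = run_association(npx, phen, cov, "secondary", seed=1)
        assert results == []
        assert info["n_screened"] == 0
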