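"""L1 solver contracts, lambda selection, repeated CV, permutation null,
selection-frequency summaries."""

import numpy as np
import pandas as pd
import pytest

import graftpop as gp
from graftpop.datamodel import AnalysisConfig
from graftpop.lasso import (fit_lasso, frequently_selected, lambda_grid,
                            lambda_max, overlap_analysis, permutation_test,
                            repeated_cv_predict, select_lambda)


def _design(rng, n=100, p=8, beta=None, noise=0.5):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"m{i}" for i in range(p)],
                     index=[f"g{j}" for j in range(n)])
    if beta is None:
        beta = np.zeros(p)
    y = pd.Series(X.to_numpy() @ beta + rng.standard_normal(n) * noise,
                  index=X.index)
    return X, y


class TestFitLasso:
    def test_unpenalized_limit_matches_ols(self, rng):
        X, y = _design(rng, beta=np.array([1.5, -2, 0, 0, 1, 0, 0, 0]))
        fit = fit_lasso(X, y, 0.0)
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        ols = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        assert np.max(np.abs(fit.beta.to_numpy() - ols[1:])) < 1e-6
        assert abs(fit.intercept - ols[0]) < 1e-6

    def test_full_shrinkage_closed_form(self, rng):
        X, y = _design(rng, beta=np.array([1.0] * 3 + [0.0] * 5))
        lmax = lambda_max(X.to_numpy(), y.to_numpy())
        fit = fit_lasso(X, y, lmax * (1 + 1e-12))
        assert (fit.beta.to_numpy() == 0.0).all()
        assert fit.intercept == pytest.approx(float(y.mean()), rel=1e-12)
        assert fit.nonzero_support == frozenset()
        # just below lambda_max at least one coefficient activates
        fit2 = fit_lasso(X, y, lmax * 0.99)
        assert len(fit2.nonzero_support) >= 1

    def test_univariate_soft_threshold_closed_form(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        y = pd.Series(0.7 * x + rng.standard_normal(n) * 0.3)
        X = pd.DataFrame({"m0": x})
        for lam in (0.05, 0.2, 0.5, 1.0):
            fit = fit_lasso(X, y, lam)
            xs = (x - x.mean()) / x.std(ddof=0)
            rho = float(xs @ (y - y.mean())) / n
            want = np.sign(rho) * max(abs(rho) - lam, 0.0) / x.std(ddof=0)
            assert fit.beta["m0"] == pytest.approx(want, abs=1e-8)

    def test_zero_variance_column_excluded(self, rng):
        X, y = _design(rng, beta=np.array([1.0] + [0.0] * 7))
        X["flat"] = 3.0
        fit = fit_lasso(X, y, 0.01)
        assert fit.beta["flat"] == 0.0
        assert "flat" not in fit.nonzero_support

    def test_nonfinite_rejected(self, rng):
        X, y = _design(rng)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_lasso(X, y, 0.1)

    def test_prediction_on_original_scale(self, rng):
        """Coefficients are reported unstandardized: predictions from the
        returned intercept/beta reproduce the standardized-model fit."""
        beta = np.array([2.0, 0, 0, -1.0, 0, 0, 0, 0])
        X, y = _design(rng, beta=beta, noise=0.1)
        X = X * 10.0 + 5.0  # far-from-standard columns
        y = pd.Series(X.to_numpy() @ beta / 10.0, index=X.index)
        fit = fit_lasso(X, y, 0.001)
        pred = fit.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.999


class TestSelectLambda:
    def test_pure_noise_selects_near_top_of_grid(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = _design(rng, n=80, p=10, noise=1.0)
            lam, grid = select_lambda(X, y, 5, seed=seed, n_lambda=50)
            hits += lam >= grid[len(grid) // 4]  # top quarter of the grid
        assert hits >= 18

    def test_strong_signal_admits_true_predictors(self):
        hits = 0
        beta = np.array([1.0, 1.0, 1.0] + [0.0] * 7)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = _design(rng, n=120, p=10, beta=beta, noise=0.85)
            lam, _ = select_lambda(X, y, 10, seed=seed, n_lambda=50)
            fit = fit_lasso(X, y, lam)
            hits += {"m0", "m1", "m2"} <= set(fit.nonzero_support)
        assert hits >= 9

    def test_leave_one_out_boundary(self, rng):
        X, y = _design(rng, n=20, p=3,
                       beta=np.array([1.0, 0.0, 0.0]), noise=0.3)
        lam, grid = select_lambda(X, y, inner_folds=20, seed=0,
                                  n_lambda=20)
        assert lam in grid

    def test_one_se_rule_never_smaller_than_min_rule(self):
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            beta = np.array([1.0, 1.0] + [0.0] * 6)
            X, y = _design(rng, n=80, p=8, beta=beta, noise=0.8)
            lam_min, _ = select_lambda(X, y, 5, seed=seed, n_lambda=40,
                                       rule="min")
            lam_1se, _ = select_lambda(X, y, 5, seed=seed, n_lambda=40,
                                       rule="1se")
            assert lam_1se >= lam_min

    def test_degenerate_response_rejected(self, rng):
        X, _ = _design(rng, n=30, p=3)
        y = pd.Series(np.ones(30), index=X.index)
        with pytest.raises(ValueError):
            select_lambda(X, y, 5, seed=0)

    def test_grid_shape(self, rng):
        X, y = _design(rng, beta=np.array([1.0] + [0.0] * 7))
        grid = lambda_grid(X.to_numpy(), y.to_numpy(), 100, 1e-4)
        assert len(grid) == 100
        assert grid[0] == pytest.approx(
            lambda_max(X.to_numpy(), y.to_numpy()))
        assert grid[-1] == pytest.approx(grid[0] * 1e-4)
        assert (np.diff(grid) < 0).all()


class TestRepeatedCV:
    CFG = dict(outer_repeats=2, outer_folds=5, inner_folds=5, n_lambda=40)

    def test_perfect_signal_predictability_near_one(self):
        rng = np.random.default_rng(0)
        beta = np.zeros(10)
        beta[:3] = 1.0
        X, y = _design(rng, n=80, p=10, beta=beta, noise=1e-6)
        cfg = AnalysisConfig(rng_seed=0, **self.CFG)
        rep = repeated_cv_predict(X, y, cfg)
        assert rep.mean_predictability > 0.999
        assert (rep.predictabilities > 0.99).all()

    def test_null_predictability_near_zero(self):
        rng = np.random.default_rng(1)
        X, y = _design(rng, n=120, p=10, noise=1.0)
        cfg = AnalysisConfig(rng_seed=1, **self.CFG)
        rep = repeated_cv_predict(X, y, cfg)
        assert abs(rep.mean_predictability) < 0.1

    def test_report_shape_and_frequencies(self):
        rng = np.random.default_rng(2)
        beta = np.zeros(8)
        beta[0] = 2.0
        X, y = _design(rng, n=60, p=8, beta=beta, noise=0.3)
        cfg = AnalysisConfig(rng_seed=2, **self.CFG)
        rep = repeated_cv_predict(X, y, cfg)
        assert rep.n_fits == len(rep.predictabilities) == 10
        assert rep.selection_frequency.max() <= rep.n_fits
        assert rep.selection_frequency["m0"] == rep.n_fits

    def test_bit_identical_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = _design(rng, n=50, p=6, noise=1.0)
        cfg = AnalysisConfig(rng_seed=9, **self.CFG)
        r1 = repeated_cv_predict(X, y, cfg)
        r2 = repeated_cv_predict(X, y, cfg)
        assert np.array_equal(r1.predictabilities, r2.predictabilities)
        assert r1.selection_frequency.equals(r2.selection_frequency)

    def test_train_only_standardization_guard(self):
        """Corrupting held-out rows must not change the trained model when
        standardization is train-only; the deliberate-leakage mutant is
        sensitive to the same corruption, showing the guard is
        load-bearing."""
        rng = np.random.default_rng(4)
        beta = np.zeros(6)
        beta[0] = 1.0
        X, y = _design(rng, n=50, p=6, beta=beta, noise=0.5)
        test_rows = X.index[:10]
        train_rows = X.index[10:]
        Xc = X.copy()
        Xc.loc[test_rows] = Xc.loc[test_rows] * 50.0 + 7.0

        lam = 0.05
        fit_clean = fit_lasso(X.loc[train_rows], y.loc[train_rows], lam)
        fit_corrupt = fit_lasso(Xc.loc[train_rows], y.loc[train_rows], lam)
        # guard: the trained model ignores held-out rows entirely (up to
        # floating-point summation order)
        np.testing.assert_allclose(fit_clean.beta.to_numpy(),
                                   fit_corrupt.beta.to_numpy(),
                                   rtol=0, atol=1e-12)

        leak_clean = fit_lasso(X.loc[train_rows], y.loc[train_rows], lam,
                               stats_rows=X.to_numpy(dtype=float))
        leak_corrupt = fit_lasso(Xc.loc[train_rows], y.loc[train_rows], lam,
                                 stats_rows=Xc.to_numpy(dtype=float))
        assert not np.allclose(leak_clean.beta.to_numpy(),
                               leak_corrupt.beta.to_numpy())


class TestPermutationTest:
    def test_planted_signal_significant(self):
        rng = np.random.default_rng(5)
        beta = np.zeros(10)
        beta[:3] = 1.0
        X, y = _design(rng, n=100, p=10, beta=beta, noise=1.0)
        cfg = AnalysisConfig(rng_seed=5, outer_repeats=1, outer_folds=5,
                             inner_folds=5, n_lambda=30,
                             permutations_per_prediction=20)
        rep = repeated_cv_predict(X, y, cfg)
        rep = permutation_test(X, y, cfg, rep)
        assert rep.empirical_p <= 0.05
        assert len(rep.null_distribution) == 100
        # permuted-response predictability centers near 0
        assert abs(rep.null_distribution.mean()) < 0.1

    def test_smoothed_estimator_never_zero(self):
        rng = np.random.default_rng(6)
        beta = np.zeros(6)
        beta[0] = 3.0
        X, y = _design(rng, n=60, p=6, beta=beta, noise=0.2)
        cfg = AnalysisConfig(rng_seed=6, outer_repeats=1, outer_folds=5,
                             inner_folds=5, n_lambda=30,
                             permutations_per_prediction=10)
        rep = permutation_test(X, y, cfg, repeated_cv_predict(X, y, cfg))
        assert rep.empirical_p == pytest.approx(1.0 / 51.0)


class TestSelectionSummaries:
    def test_threshold_is_inclusive(self):
        freq = {"shikimate": 100, "glutamate": 100, "caffeate": 94,
                "quinate": 95}
        out = frequently_selected(freq, threshold=95, n_fits=100)
        assert out == ["glutamate", "shikimate", "quinate"]

    def test_empty_and_zero_threshold(self):
        assert frequently_selected({}, 95) == []
        out = frequently_selected({"a": 1, "b": 5}, threshold=0)
        assert out == ["b", "a"]

    def test_scaled_fit_counts(self):
        # 48/50 fits is 96% and passes the 95% rule; 47/50 does not
        assert frequently_selected({"x": 48}, 95, n_fits=50) == ["x"]
        assert frequently_selected({"x": 47}, 95, n_fits=50) == []

    def test_overlap_partition(self):
        cells = overlap_analysis({"T1": ["a", "b", "c"],
                                  "T2": ["b", "c", "d"],
                                  "T3": ["c"]})
        assert cells[("T1",)] == ["a"]
        assert cells[("T1", "T2")] == ["b"]
        assert cells[("T1", "T2", "T3")] == ["c"]
        assert cells[("T2",)] == ["d"]

    def test_disjoint_and_identical(self):
        cells = overlap_analysis({"T1": ["a", "b"], "T2": ["c"]})
        assert cells == {("T1",): ["a", "b"], ("T2",): ["c"]}
        cells = overlap_analysis({"T1": ["a"], "T2": ["a"]})
        assert cells == {("T1", "T2"): ["a"]}

    def test_overlap_needs_two_reports(self):
        with pytest.raises(ValueError):
            overlap_analysis({"T1": ["a"]})
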