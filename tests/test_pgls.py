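"""PGLS fitting, lambda profiling, residual diagnostics and outlier loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import dense_gls, make_regression_data, pic_slope_through_origin
from frogeye.pgls import (
    design_matrix,
    gls_fit,
    iterative_outlier_refit,
    parse_formula,
    profile_lambda,
    studentized_residuals,
)
from frogeye.phylo import PhyloCovariance, apply_lambda, phylo_covariance


def _simple_X(x: pd.Series) -> pd.DataFrame:
    return design_matrix(pd.DataFrame({"x": x}), ["x"])


class TestFormulaAndDesign:
    def test_parse_simple(self):
        assert parse_formula("ED_log ~ RM_log") == ("ED_log", ["RM_log"], False)

    def test_parse_interaction(self):
        resp, terms, inter = parse_formula("ED_log ~ RM_log * adult_habitat")
        assert resp == "ED_log" and inter and terms == ["RM_log", "adult_habitat"]

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            parse_formula("no tilde here")

    def test_treatment_coding_reference_level(self):
        data = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                "f": ["b", "a", "c", "a", "c", "b", "a", "c"],
            },
            index=list("stuvwxyz"),
        )
        X = design_matrix(data, ["x", "f"], interaction=True)
        # alphabetically first level 'a' is the reference
        assert list(X.columns) == ["Intercept", "x", "f[b]", "f[c]", "x:f[b]", "x:f[c]"]
        assert X.loc["s", "f[b]"] == 1.0 and X.loc["t", "f[b]"] == 0.0
        assert X.loc["u", "x:f[c]"] == 3.0

    def test_single_level_factor_errors(self):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0], "f": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            design_matrix(data, ["x", "f"])


class TestGLSFit:
    def test_exact_line_any_covariance(self, hand_tree):
        cov = phylo_covariance(hand_tree)
        x = pd.Series([0.0, 1.0, 2.0], index=cov.taxa)
        fit = gls_fit(_simple_X(x), x.rename("y"), cov)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_star_tree_reduces_to_ols(self, star_tree, rng):
        cov = phylo_covariance(star_tree)
        x = pd.Series(rng.normal(size=5), index=cov.taxa)
        y = pd.Series(rng.normal(size=5), index=cov.taxa)
        fit = gls_fit(_simple_X(x), y, cov)
        b_ols = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(b_ols[0], abs=1e-10)
        assert fit.intercept == pytest.approx(b_ols[1], abs=1e-10)

    def test_hand_tree_dense_matrix_oracle(self, hand_tree):
        cov = phylo_covariance(hand_tree)
        x = pd.Series([0.0, 1.0, 2.0], index=cov.taxa)
        y = pd.Series([0.0, 1.0, 1.0], index=cov.taxa)
        X = _simple_X(x)
        fit = gls_fit(X, y, cov)
        beta = dense_gls(X.to_numpy(), y.to_numpy(), cov.matrix)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)

    @pytest.mark.parametrize("n_tips,seed", [(20, 1), (87, 2), (220, 3)])
    def test_whitened_equals_dense_oracle_random_trees(self, n_tips, seed):
        _, cov, X, y, _ = make_regression_data(n_tips, seed)
        fit = gls_fit(X, y, cov)
        beta = dense_gls(X.to_numpy(), y.to_numpy(), cov.matrix)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_rank_deficient_design_errors(self):
        taxa = [f"t{i}" for i in range(6)]
        cov = PhyloCovariance(taxa, np.eye(6), 1.0)
        x = np.arange(6.0)
        X = pd.DataFrame(
            {"Intercept": np.ones(6), "x": x, "x2": 2.0 * x}, index=taxa
        )
        y = pd.Series(x, index=taxa)
        with pytest.raises(ValueError, match="rank"):
            gls_fit(X, y, cov)

    def test_singular_covariance_errors(self):
        taxa = ["A", "B", "C", "D"]
        C = np.ones((4, 4))
        cov = PhyloCovariance(taxa, C, 1.0)
        X = pd.DataFrame({"Intercept": np.ones(4), "x": np.arange(4.0)}, index=taxa)
        y = pd.Series(np.arange(4.0), index=taxa)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gls_fit(X, y, cov)

    def test_misaligned_order_errors(self, hand_tree):
        cov = phylo_covariance(hand_tree)
        x = pd.Series([0.0, 1.0, 2.0], index=list(reversed(cov.taxa)))
        with pytest.raises(ValueError, match="order"):
            gls_fit(_simple_X(x), x.rename("y"), cov)


class TestProfileLambda:
    def test_grid_search_oracle(self):
        _, cov, X, y, _ = make_regression_data(60, 17, lam=0.7)
        fit = profile_lambda(X, y, cov)
        grid = np.arange(0.0, 1.0005, 0.001)
        ll = [gls_fit(X, y, apply_lambda(cov, g)).log_likelihood for g in grid]
        assert fit.lambda_ == pytest.approx(grid[int(np.argmax(ll))], abs=0.01)

    def test_optimum_beats_boundaries(self):
        _, cov, X, y, _ = make_regression_data(40, 23, lam=0.5)
        fit = profile_lambda(X, y, cov)
        for lam in (0.0, 1.0):
            assert fit.log_likelihood >= (
                gls_fit(X, y, apply_lambda(cov, lam)).log_likelihood - 1e-9
            )

    def test_star_tree_flat_likelihood(self, star_tree, rng):
        cov = phylo_covariance(star_tree)
        x = pd.Series(rng.normal(size=5), index=cov.taxa)
        y = pd.Series(rng.normal(size=5), index=cov.taxa)
        fit = profile_lambda(_simple_X(x), y, cov)
        assert fit.lambda_ == 0.0
        assert fit.lambda_profile_flat

    def test_recovers_simulated_lambda(self):
        # median over replicates at the default study-scale condition
        lams = []
        for rep in range(12):
            _, cov, X, y, _ = make_regression_data(220, 300 + rep)
            lams.append(profile_lambda(X, y, cov).lambda_)
        assert np.median(lams) == pytest.approx(0.96, abs=0.05)


class TestStudentizedResiduals:
    def test_perfect_fit_gives_zeros(self):
        _, cov, X, _, _ = make_regression_data(12, 29)
        y = (0.5 + 2.0 * X["x"]).rename("y")
        fit = gls_fit(X, y, cov)
        assert np.allclose(studentized_residuals(fit), 0.0)

    def test_matches_ols_external_studentized_on_identity_cov(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.stats.outliers_influence import OLSInfluence

        n = 40
        taxa = [f"t{i:02d}" for i in range(n)]
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        cov = PhyloCovariance(taxa, np.eye(n), 1.0)
        X = design_matrix(pd.DataFrame({"x": x}, index=taxa), ["x"])
        fit = gls_fit(X, pd.Series(y, index=taxa), cov)
        ours = studentized_residuals(fit).to_numpy()
        theirs = OLSInfluence(
            sm.OLS(y, sm.add_constant(x)).fit()
        ).resid_studentized_external
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_planted_outlier_attains_max(self):
        tree, cov, X, y, cfg = make_regression_data(80, 31)
        victim = y.index[13]
        y = y.copy()
        y[victim] += 10 * np.sqrt(cfg.sigma2 * np.mean(np.diag(cov.matrix)))
        fit = profile_lambda(X, y, cov)
        t = studentized_residuals(fit)
        assert t.abs().idxmax() == victim
        assert t.abs().max() > 3


class TestOutlierRefit:
    def test_clean_data_no_removals(self):
        _, cov, X, y, _ = make_regression_data(50, 41, sigma2=1e-4)
        report = iterative_outlier_refit(X, y, cov)
        if not report.iterations:  # clean draw: final == initial
            assert report.final_fit.params.equals(report.initial_fit.params)
            assert report.parameter_drift.abs().max() == 0.0

    def test_planted_outlier_removed_and_slope_recovers(self):
        tree, cov, X, y_clean, cfg = make_regression_data(100, 43)
        clean_slope = profile_lambda(X, y_clean, cov).slope
        victim = y_clean.index[7]
        y = y_clean.copy()
        y[victim] += 10 * np.sqrt(cfg.sigma2 * np.mean(np.diag(cov.matrix)))
        report = iterative_outlier_refit(X, y, cov)
        assert victim in report.removed_taxa
        # removal pulls the slope back toward the outlier-free estimate
        err_before = abs(report.initial_fit.slope - clean_slope)
        err_after = abs(report.final_fit.slope - clean_slope)
        assert err_after < err_before
        # drift small relative to the initial standard error (sensitivity check)
        assert abs(report.parameter_drift["x"]) < report.initial_fit.bse["x"]

    def test_final_fit_has_no_exceedances(self):
        _, cov, X, y, _ = make_regression_data(60, 47)
        report = iterative_outlier_refit(X, y, cov, threshold=2.5)
        t = studentized_residuals(report.final_fit)
        assert (t.abs() <= 2.5).all()


class TestEquivalences:
    """Classic GLS identities on simulated trees."""

    @pytest.mark.parametrize("seed", [5, 6])
    def test_lambda_zero_equals_ols_on_ultrametric_tree(self, seed):
        _, cov, X, y, _ = make_regression_data(40, seed)
        fit = gls_fit(X, y, apply_lambda(cov, 0.0))
        b = np.polyfit(X["x"], y, 1)
        assert fit.slope == pytest.approx(b[0], abs=1e-8)
        assert fit.intercept == pytest.approx(b[1], abs=1e-8)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_lambda_one_slope_equals_pic_through_origin(self, seed):
        tree, cov, X, y, _ = make_regression_data(64, seed, lam=1.0)
        fit = gls_fit(X, y, cov)
        assert fit.slope == pytest.approx(
            pic_slope_through_origin(tree, X["x"], y), abs=1e-8
        )

    def test_coefficients_unbiased_in_simulation(self):
        slopes = []
        for rep in range(200):
            _, cov, X, y, cfg = make_regression_data(24, 900 + rep)
            slopes.append(gls_fit(X, y, apply_lambda(cov, cfg.lambda_true)).slope)
        slopes = np.asarray(slopes)
        mc_se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.82) < 2 * mc_se + 1e-12
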