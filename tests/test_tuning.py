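"""Grids, cross-validation curves, information criteria and closed forms."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

from pcscreen.core import center_columns, edge_set
from pcscreen.estimators import fit_nodewise_lasso
from pcscreen.simulation import sample_mvn, toy_model
from pcscreen.tuning import (
    CvCurve,
    LambdaGrid,
    VARIANTS,
    _glasso_path,
    cv1_glasso,
    cv2_glasso,
    cv_nodewise,
    cv_select,
    cv_space,
    ebic_glasso,
    bic_nodewise,
    bic_space,
    fsr_lambda,
    glasso_grid,
    glmnet_like_grid,
    make_folds,
    space_grid,
    tune_lambda,
)


def normal_quantile_oracle(q):
    """Independent standard-normal quantile via root-finding on the CDF."""
    cdf = lambda x: 0.5 * (1.0 + erf(x / np.sqrt(2.0))) - q
    return brentq(cdf, -10, 10, xtol=1e-13)


class TestFolds:
    def test_sizes_and_determinism(self):
        labels = make_folds(103, 10, seed=5)
        sizes = np.bincount(labels)
        assert set(sizes) <= {10, 11}
        assert np.array_equal(labels, make_folds(103, 10, seed=5))
        assert not np.array_equal(labels, make_folds(103, 10, seed=6))

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 1)


class TestGrids:
    def test_glasso_grid_endpoints(self):
        S = toy_model().sigma
        grid = glasso_grid(S, 6)
        assert len(grid) == 100
        assert grid.values[0] == pytest.approx(0.001)
        assert grid.values[-1] == pytest.approx(1.68)
        step = np.diff(grid.values)
        assert np.allclose(step, step[0])

    def test_glasso_grid_highdim_lower_endpoint(self, rng):
        A = rng.standard_normal((300, 150))
        S = A.T @ A / 300 + np.eye(150)
        assert glasso_grid(S, 150).values[0] == pytest.approx(0.05)

    def test_space_grid_quantile_oracle(self):
        grid = space_grid(100, 20)
        lo = 10 * normal_quantile_oracle(1 - 0.9 / 800)
        hi = 10 * normal_quantile_oracle(1 - 1e-4 / 800)
        assert grid.values[0] == pytest.approx(lo, abs=1e-9)
        assert grid.values[-1] == pytest.approx(hi, abs=1e-9)
        assert len(grid) == 100

    def test_space_grid_sqrt_n_scaling(self):
        g1, g4 = space_grid(100, 10), space_grid(400, 10)
        assert np.allclose(g4.values, 2.0 * g1.values)

    def test_glmnet_grid_lambda_max_zeroes_node(self, toy_data):
        grid = glmnet_like_grid(toy_data, 0)
        assert len(grid) == 100
        ratios = grid.values[1:] / grid.values[:-1]
        assert np.allclose(ratios, ratios[0])  # log-equidistant
        fit, _ = fit_nodewise_lasso(toy_data, grid.values[-1] * (1 + 1e-10))
        assert np.abs(fit.beta[0]).max() == 0.0

    def test_glmnet_grid_lambda_max_brute_force(self, toy_data):
        """lambda_max equals the largest absolute predictor-response inner
        product (per observation), found here by direct scan."""
        n = toy_data.shape[0]
        best = max(
            abs(toy_data[:, j] @ toy_data[:, 2]) / n for j in range(6) if j != 2
        )
        assert glmnet_like_grid(toy_data, 2).values[-1] == pytest.approx(best)


class TestCvSelect:
    def hand_curve(self):
        grid = LambdaGrid(np.array([1.0, 2.0, 3.0]), "equidistant", "glasso")
        # per-fold losses chosen so that: sums = [24, 25, 40]; at the
        # minimizer sd(10,14)=2sqrt(2), se=2; band = 26 admits lambda=2 only
        return CvCurve(grid, np.array([[10.0, 12.0, 20.0], [14.0, 13.0, 20.0]]))

    def test_min_rule_hand_example(self):
        res = cv_select(self.hand_curve(), "min")
        assert res.selected == 1.0

    def test_one_se_rule_hand_example(self):
        res = cv_select(self.hand_curve(), "one_se")
        assert res.selected == 2.0

    def test_flat_curve_picks_most_regularized(self):
        grid = LambdaGrid(np.array([0.1, 0.2, 0.3]), "equidistant", "glasso")
        curve = CvCurve(grid, np.full((3, 3), 5.0))
        assert cv_select(curve, "min").selected == 0.3
        assert cv_select(curve, "one_se").selected == 0.3

    def test_one_se_never_below_min_rule(self, toy_data):
        S = np.cov(toy_data, rowvar=False, bias=True)
        grid = glasso_grid(S, 6)
        folds = make_folds(100, 10, seed=3)
        curve = cv1_glasso(toy_data, grid, folds)
        assert cv_select(curve, "one_se").selected >= cv_select(curve, "min").selected

    def test_nan_losses_flagged(self):
        grid = LambdaGrid(np.array([1.0, 2.0]), "equidistant", "glasso")
        curve = CvCurve(grid, np.array([[np.nan, 1.0], [np.nan, 2.0]]))
        res = cv_select(curve, "min")
        assert res.had_nan and res.selected == 2.0


class TestGlassoCv:
    def test_losses_reproducible_under_seed(self, toy_data):
        S = np.cov(toy_data, rowvar=False, bias=True)
        grid = LambdaGrid(np.linspace(0.05, 1.6, 8), "equidistant", "glasso")
        folds = make_folds(100, 10, seed=9)
        c1 = cv1_glasso(toy_data, grid, folds)
        c2 = cv1_glasso(toy_data, grid, folds)
        assert np.array_equal(c1.fold_losses, c2.fold_losses)

    def test_cv2_full_shrinkage_loss_is_total_sum_of_squares(self, toy_data):
        """A diagonal precision predicts zero for every node, so each fold's
        loss is the held-out total sum of squares."""
        S = np.cov(toy_data, rowvar=False, bias=True)
        # 2x the full-sample off-diagonal max so every training-fold
        # covariance is fully shrunk as well
        lam = float(2.0 * np.abs(S - np.diag(np.diag(S))).max())
        grid = LambdaGrid(np.array([lam, lam * 1.1]), "equidistant", "glasso")
        folds = make_folds(100, 5, seed=1)
        curve = cv2_glasso(toy_data, grid, folds)
        for fold in range(5):
            expected = float((toy_data[folds == fold] ** 2).sum())
            assert curve.fold_losses[fold, 0] == pytest.approx(expected, rel=1e-10)

    def test_cv_losses_non_negative(self, toy_data):
        grid = LambdaGrid(np.linspace(0.2, 1.6, 5), "equidistant", "glasso")
        folds = make_folds(100, 5, seed=2)
        assert (cv2_glasso(toy_data, grid, folds).fold_losses >= 0).all()


class TestInformationCriteria:
    def test_ebic_gamma_zero_is_bic(self, toy_data):
        S = np.cov(toy_data, rowvar=False, bias=True)
        grid = glasso_grid(S, 6)
        bic = ebic_glasso(toy_data, grid, gamma=0.0)
        ebic0 = ebic_glasso(toy_data, grid, gamma=0.0)
        assert bic.selected == ebic0.selected
        assert np.allclose(bic.criterion, ebic0.criterion, equal_nan=True)

    def test_ebic_penalty_arithmetic(self, toy_data):
        """EBIC(gamma) - BIC = 4 * kappa * gamma * log p entrywise, with
        kappa the count of nonzero off-diagonal precision entries."""
        S = np.cov(toy_data, rowvar=False, bias=True)
        grid = LambdaGrid(np.linspace(0.2, 1.6, 6), "equidistant", "glasso")
        bic = ebic_glasso(toy_data, grid, gamma=0.0)
        ebic = ebic_glasso(toy_data, grid, gamma=0.5)
        kappas = np.array(
            [2 * len(edge_set(f.partial_correlations())) for f in _glasso_path(S, grid)]
        )
        expected = 4.0 * kappas * 0.5 * np.log(6)
        assert np.allclose(ebic.criterion - bic.criterion, expected)

    def test_ebic_never_less_sparse_than_bic(self, toy_data):
        S = np.cov(toy_data, rowvar=False, bias=True)
        grid = glasso_grid(S, 6)
        assert ebic_glasso(toy_data, grid, 0.5).selected >= ebic_glasso(toy_data, grid, 0.0).selected

    def test_bic_nodewise_null_model_criterion(self, toy_data):
        """At lambda_max the neighborhood is empty and the criterion equals
        the node's total sum of squares."""
        grid = glmnet_like_grid(toy_data, 0)
        res = bic_nodewise(toy_data, 0, grid)
        assert res.criterion[-1] == pytest.approx(float((toy_data[:, 0] ** 2).sum()))

    def test_bic_nodewise_flips_at_log_n(self, rng):
        """Empty and one-edge models trade places exactly when the residual
        sum-of-squares gain crosses log n."""
        n = 100
        x = center_columns(rng.standard_normal((n, 1)))[:, 0]
        for strength in (0.05, 0.5):
            y = strength * x + center_columns(rng.standard_normal((n, 1)))[:, 0]
            X = center_columns(np.column_stack([y, x]))
            grid = glmnet_like_grid(X, 0)
            res = bic_nodewise(X, 0, grid)
            rss0 = float((X[:, 0] ** 2).sum())
            beta_ols = (X[:, 1] @ X[:, 0]) / (X[:, 1] @ X[:, 1])
            rss1 = float(((X[:, 0] - beta_ols * X[:, 1]) ** 2).sum())
            if rss0 - rss1 > np.log(n) + 1.0:
                assert res.criterion.min() < rss0  # one-edge model wins
            # in all cases the null end of the path scores rss0
            assert res.criterion[-1] == pytest.approx(rss0)

    def test_bic_space_null_model(self, toy_data):
        n = toy_data.shape[0]
        lam = 1e4  # far beyond full shrinkage
        grid = LambdaGrid(np.array([lam, 2 * lam]), "equidistant", "space")
        res = bic_space(toy_data, grid)
        assert res.criterion[0] == pytest.approx(float((toy_data**2).sum()), rel=1e-8)


class TestFsr:
    def test_closed_forms_match_quantile_oracle(self):
        q = normal_quantile_oracle(1 - 0.05 / 800)
        assert fsr_lambda(100, 20, 0.05, "nr") == pytest.approx(0.2 * q, abs=1e-10)
        assert fsr_lambda(100, 20, 0.05, "space") == pytest.approx(10 * q, abs=1e-10)

    def test_monotone_decreasing_in_alpha(self):
        vals = [fsr_lambda(100, 20, a, "nr") for a in (0.01, 0.05, 0.2, 0.5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_domain_error(self, alpha):
        with pytest.raises(ValueError):
            fsr_lambda(100, 20, alpha, "nr")


class TestNodewiseAndSpaceCv:
    def test_nodewise_null_loss_at_lambda_max(self, toy_data):
        grid = glmnet_like_grid(toy_data, 0)
        folds = make_folds(100, 5, seed=4)
        curve = cv_nodewise(toy_data, 0, grid, folds, penalty="lasso")
        # lambda_max for the full sample need not zero every training-fold
        # fit, but losses are non-negative and reproducible
        assert (curve.fold_losses >= 0).all()
        again = cv_nodewise(toy_data, 0, grid, folds, penalty="lasso")
        assert np.array_equal(curve.fold_losses, again.fold_losses)

    def test_space_full_shrinkage_loss(self, toy_data):
        lam = 1e4
        grid = LambdaGrid(np.array([lam, 2 * lam]), "equidistant", "space")
        folds = make_folds(100, 5, seed=6)
        curve = cv_space(toy_data, grid, folds)
        for fold in range(5):
            expected = float((toy_data[folds == fold] ** 2).sum())
            assert curve.fold_losses[fold, 0] == pytest.approx(expected, rel=1e-8)


class TestTuneLambda:
    @pytest.mark.parametrize("method,tuning", VARIANTS)
    def test_every_variant_selects_a_penalty(self, toy_data, method, tuning):
        lam, _ = tune_lambda(toy_data, method, tuning, k=5, seed=0)
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        assert (lam > 0).all()

    def test_unsupported_combination_rejected(self, toy_data):
        with pytest.raises(ValueError):
            tune_lambda(toy_data, "ridge", "fsr")
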