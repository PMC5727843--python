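import numpy as np
import pytest

from sasangdx.lasso import (
    LambdaPath,
    class_weights,
    cv_select_lambda,
    default_lambda_grid,
    lambda_max,
    lasso_fit,
)


def soft_threshold(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def prox_gradient_lasso(X, y, w, lam, n_iter=200_000, tol=1e-12):
    """Independent FISTA solver for
    (1/2W) sum w_i (y_i - b0 - x_i b)^2 + lam * |b|_1,
    with the intercept profiled out via weighted centering."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    W = w.sum()
    xbar = (w[:, None] * X).sum(axis=0) / W
    ybar = (w * y).sum() / W
    Xc, yc = X - xbar, y - ybar
    A = (Xc * w[:, None]).T @ Xc / W
    b = (Xc * w[:, None]).T @ yc / W
    L = np.linalg.eigvalsh(A).max()
    beta = np.zeros(X.shape[1])
    z, t = beta.copy(), 1.0
    for _ in range(n_iter):
        grad = A @ z - b
        new = soft_threshold(z - grad / L, lam / L)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = new + (t - 1) / t_new * (new - beta)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta, t = new, t_new
    return beta, ybar - xbar @ beta


class TestClassWeights:
    def test_closed_form(self):
        labels = ["TE"] * 100 + ["SE"] * 50 + ["SY"] * 50
        w = class_weights(labels)
        np.testing.assert_allclose(w[:100], 2 / 3)
        np.testing.assert_allclose(w[100:], 4 / 3)

    def test_equal_counts_give_unit_weights(self):
        w = class_weights(["TE", "SE", "SY"] * 7)
        np.testing.assert_allclose(w, 1.0)

    def test_equal_total_mass_per_class(self, rng):
        """Exact identity: each class's weights sum to N/3."""
        for _ in range(10):
            n = int(rng.integers(30, 300))
            labels = rng.choice(["TE", "SE", "SY"], n,
                                p=[0.5, 0.2, 0.3])
            if len(set(labels)) < 3:
                continue
            w = class_weights(labels)
            for t in ("TE", "SE", "SY"):
                assert w[labels == t].sum() == pytest.approx(n / 3)
            assert w.mean() == pytest.approx(1.0)

    def test_absent_class_is_an_error(self):
        with pytest.raises(ValueError):
            class_weights(["TE", "SE", "TE"])


class TestLassoFit:
    def test_penalty_dominant_limit(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        w = rng.uniform(0.5, 2.0, 40)
        lam = lambda_max(X, y, w) * 1.001
        fit = lasso_fit(X, y, w, lam=lam)
        np.testing.assert_array_equal(fit.coef, 0.0)
        assert fit.intercept == pytest.approx((w * y).sum() / w.sum())

    def test_soft_threshold_closed_form_on_orthonormal_design(self, rng):
        """With zero-mean columns satisfying (1/n) X'X = I and unit
        weights, the solution is the soft-thresholded OLS estimate."""
        n, p = 64, 5
        raw = rng.standard_normal((n, p))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        X = np.sqrt(n) * q[:, :p]
        beta_true = np.array([2.0, -1.0, 0.5, 0.0, 3.0])
        y = X @ beta_true + rng.standard_normal(n)
        ols = X.T @ (y - y.mean()) / n
        for lam in (0.05, 0.3, 1.0):
            fit = lasso_fit(X, y, lam=lam, standardize=False)
            np.testing.assert_allclose(fit.coef, soft_threshold(ols, lam),
                                       atol=1e-8)

    def test_zero_penalty_matches_weighted_normal_equations(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        w = rng.uniform(0.2, 3.0, 10)
        fit = lasso_fit(X, y, w, lam=0.0, standardize=False)
        D = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(D.T @ (w[:, None] * D), D.T @ (w * y))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-8)

    def test_matches_proximal_gradient_oracle(self, rng):
        """Coordinate-descent solution agrees with an independent FISTA
        solver on random weighted 12x5 instances."""
        for _ in range(20):
            X = rng.standard_normal((12, 5)) * rng.uniform(0.5, 2.0, 5)
            y = rng.standard_normal(12)
            w = rng.uniform(0.3, 3.0, 12)
            lam = rng.uniform(0.01, 0.5)
            fit = lasso_fit(X, y, w, lam=lam, standardize=False)
            beta, b0 = prox_gradient_lasso(X, y, w, lam)
            np.testing.assert_allclose(fit.coef, beta, atol=1e-6)
            assert fit.intercept == pytest.approx(b0, abs=1e-6)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[1.0], [np.nan]]), np.array([0.0, 1.0]), lam=0.1)

    def test_duplicated_collinear_column_leaves_predictions_unchanged(self, rng):
        X = rng.standard_normal((60, 4))
        y = X[:, 0] * 1.5 + rng.standard_normal(60) * 0.5
        fit1 = lasso_fit(X, y, lam=0.1)
        Xdup = np.column_stack([X, X[:, 0]])
        fit2 = lasso_fit(Xdup, y, lam=0.1)
        np.testing.assert_allclose(fit2.predict(Xdup), fit1.predict(X), atol=1e-6)


class TestWeightDuplicationEquivalence:
    def test_weighted_fit_equals_duplicated_data_fit(self, rng):
        """Class weights from counts (100, 50, 50) reproduce, at any
        penalty, the unweighted fit on data where each minority row is
        duplicated to parity (integer weights 2 vs 1, rescaled)."""
        n_te, n_se, n_sy = 20, 10, 10
        labels = np.array(["TE"] * n_te + ["SE"] * n_se + ["SY"] * n_sy)
        X = rng.standard_normal((40, 5))
        y = (labels == "SE").astype(float)
        w = class_weights(labels)  # TE: 2/3, others: 4/3 -> ratio 1:2
        dup_rows = np.concatenate([np.arange(40), np.arange(n_te, 40)])
        Xd, yd = X[dup_rows], y[dup_rows]
        for lam in (0.0, 0.05, 0.2):
            fw = lasso_fit(X, y, w, lam=lam)
            fd = lasso_fit(Xd, yd, lam=lam)
            np.testing.assert_allclose(fw.coef, fd.coef, atol=1e-6)
            assert fw.intercept == pytest.approx(fd.intercept, abs=1e-6)


class TestCVSelectLambda:
    def test_lambda_star_is_on_the_grid(self, rng):
        X = rng.standard_normal((100, 8))
        y = X[:, 0] + rng.standard_normal(100)
        path = cv_select_lambda(X, (y > 0).astype(float), folds=5, seed=3)
        assert path.lam_star in path.lambdas
        assert np.all(np.diff(path.lambdas) < 0)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((80, 6))
        y = (X[:, 1] > 0).astype(float)
        p1 = cv_select_lambda(X, y, folds=5, seed=11)
        p2 = cv_select_lambda(X, y, folds=5, seed=11)
        assert p1.lam_star == p2.lam_star
        np.testing.assert_array_equal(p1.cv_mse, p2.cv_mse)

    def test_pure_noise_selects_heavy_penalty(self):
        """On a pure-noise response the CV minimizer lands in the
        heavily penalized half of the grid (median over 20 seeds)."""
        positions = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            X = r.standard_normal((100, 10))
            y = r.choice([0.0, 1.0], 100)
            path = cv_select_lambda(X, y, folds=5, seed=seed)
            positions.append(int(np.argmin(np.abs(path.lambdas - path.lam_star))))
        assert np.median(positions) < len(path.lambdas) / 2

    def test_support_grows_along_the_path(self, rng):
        """At lambda_max no slopes are active; active sets only grow
        toward small lambda in the number of nonzeros at the ends."""
        X = rng.standard_normal((120, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.standard_normal(120) * 0.5
        lmax = lambda_max(X, y)
        grid = default_lambda_grid(lmax, 20)
        n_active = [lasso_fit(X, y, lam=l).n_active() for l in grid]
        assert n_active[0] == 0
        assert n_active[-1] == max(n_active)
        fit_first = lasso_fit(X, y, lam=grid[0])
        fit_last = lasso_fit(X, y, lam=grid[-1])
        first_set = set(np.flatnonzero(fit_first.coef))
        last_set = set(np.flatnonzero(fit_last.coef))
        assert first_set <= last_set

    def test_small_n_reduces_folds_with_warning(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1.0])
        path = cv_select_lambda(X, y, folds=10, seed=0)
        assert path.n_folds <= 6
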