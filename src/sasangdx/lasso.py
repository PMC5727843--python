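"""Class-weighted L1-penalized (LASSO) regression machinery.

All component models regress a 0/1 class indicator on features under
observation weights, minimizing

    (1 / 2W) * sum_i v_i (y_i - b0 - x_i @ beta)**2 + lam * ||beta||_1,

with W = sum_i v_i.  Features are standardized internally to weighted
mean 0 / SD 1 on the training data (the penalty acts on the
standardized scale); returned coefficients are mapped back to the
original feature scale so prediction is a plain affine map.  Class
weights v_i = N / (3 * N_j) give each of the three constitutional
types equal total mass regardless of its prevalence.

The quadratic part is solved by scikit-learn's coordinate descent
after sqrt-weight row scaling; with weights normalized to mean 1 the
``alpha`` of :class:`sklearn.linear_model.Lasso` equals ``lam`` above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

SC_TYPES = ("TE", "SE", "SY")

N_LAMBDAS = 100
LAMBDA_MIN_RATIO = 1e-3
COEF_TOL = 1e-7  # convergence tolerance on coefficient max-change
SD_FLOOR = 1e-8


def class_weights(labels: Sequence[str], classes: Sequence[str] = SC_TYPES) -> np.ndarray:
    """Per-subject weights N/(k*N_j) equalizing total mass per class.

    With all k classes present the weights sum to N within each class
    block of N/k, and their overall mean is exactly 1.
    """
    labels = np.asarray(labels)
    classes = tuple(classes)
    n = labels.size
    counts = {c: int(np.sum(labels == c)) for c in classes}
    missing = [c for c, m in counts.items() if m == 0]
    if missing:
        raise ValueError(f"class(es) absent from labels: {missing}")
    w = np.empty(n, dtype=float)
    for c, m in counts.items():
        w[labels == c] = n / (len(classes) * m)
    return w


@dataclass
class LinearFit:
    """An affine model y ≈ intercept + X @ coef on the original feature
    scale, with the standardization statistics it was fitted under."""

    coef: np.ndarray
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def n_active(self) -> int:
        return int(np.sum(self.coef != 0))

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "lam": float(self.lam),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearFit":
        return cls(np.asarray(d["coef"], dtype=float), float(d["intercept"]),
                   float(d["lam"]), np.asarray(d["feature_means"], dtype=float),
                   np.asarray(d["feature_sds"], dtype=float))


def _check_finite(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> None:
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite values in design, response or weights")


def _weighted_stats(X: np.ndarray, w: np.ndarray, standardize: bool):
    W = w.sum()
    means = (w[:, None] * X).sum(axis=0) / W
    if standardize:
        sds = np.sqrt((w[:, None] * (X - means) ** 2).sum(axis=0) / W)
        sds = np.maximum(sds, SD_FLOOR)
    else:
        sds = np.ones(X.shape[1])
    return means, sds


def _prepare(X, y, weights, standardize):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    _check_finite(X, y, w)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    means, sds = _weighted_stats(X, w, standardize)
    W = w.sum()
    ybar = float((w * y).sum() / W)
    Xs = (X - means) / sds
    sw = np.sqrt(w)
    Z = Xs * sw[:, None]
    u = (y - ybar) * sw
    return X, y, w, W, means, sds, ybar, Z, u


def lambda_max(X, y, weights=None, standardize: bool = True) -> float:
    """Smallest penalty that zeroes every slope."""
    _, _, _, W, _, _, _, Z, u = _prepare(X, y, weights, standardize)
    return float(np.max(np.abs(Z.T @ u)) / W)


def lasso_fit(
    X,
    y,
    weights=None,
    lam: float = 0.0,
    standardize: bool = True,
) -> LinearFit:
    """Weighted LASSO at a fixed penalty ``lam`` (see module objective).

    ``lam = 0`` solves the weighted least-squares problem exactly via
    normal equations (minimum-norm solution when rank deficient).
    """
    X, y, w, W, means, sds, ybar, Z, u = _prepare(X, y, weights, standardize)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0.0:
        beta_std, *_ = np.linalg.lstsq(Z, u, rcond=None)
    else:
        alpha = lam * W / n
        model = Lasso(alpha=alpha, fit_intercept=False, tol=COEF_TOL * 1e-2,
                      max_iter=200_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z, u)
        beta_std = model.coef_
    coef = beta_std / sds
    intercept = ybar - float(means @ coef)
    return LinearFit(coef=np.asarray(coef, dtype=float), intercept=intercept,
                     lam=float(lam), feature_means=means, feature_sds=sds)


@dataclass
class LambdaPath:
    """A decreasing penalty grid with per-lambda CV error and the
    minimizer lam_star."""

    lambdas: np.ndarray
    cv_mse: np.ndarray
    cv_se: np.ndarray
    lam_star: float
    n_folds: int
    seed: int

    def __post_init__(self):
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")


def default_lambda_grid(lmax: float, n: int = N_LAMBDAS,
                        min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    lmax = max(lmax, 1e-12)
    return np.geomspace(lmax, lmax * min_ratio, n)


def cv_select_lambda(
    X,
    y,
    weights=None,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = N_LAMBDAS,
    min_ratio: float = LAMBDA_MIN_RATIO,
    standardize: bool = True,
    stratify_on=None,
) -> LambdaPath:
    """Pick the penalty minimizing mean cross-validated weighted MSE.

    Folds are stratified (by the 0/1 indicator unless ``stratify_on``
    supplies class labels) and fully determined by ``seed``.  The grid
    is ``n_lambdas`` log-spaced values from the all-zero penalty
    lambda_max down to ``min_ratio * lambda_max``; ties resolve to the
    more-penalized (larger) lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    _check_finite(X, y, w)
    grid = default_lambda_grid(lambda_max(X, y, w, standardize), n_lambdas, min_ratio)
    strat = np.asarray(stratify_on) if stratify_on is not None else y
    _, strat_counts = np.unique(strat, return_counts=True)
    max_folds = min(n, int(strat_counts.min()))
    if folds > max_folds:
        log.warning("reducing fold count %d -> %d (smallest stratum)",
                    folds, max(2, max_folds))
        folds = max(2, max_folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((folds, grid.size))
    fold_w = np.zeros(folds)
    for f, (tr, te) in enumerate(skf.split(X, strat)):
        Xtr, ytr, wtr = X[tr], y[tr], w[tr]
        means, sds = _weighted_stats(Xtr, wtr, standardize)
        Wtr = wtr.sum()
        ybar = float((wtr * ytr).sum() / Wtr)
        sw = np.sqrt(wtr)
        Z = ((Xtr - means) / sds) * sw[:, None]
        u = (ytr - ybar) * sw
        alphas = grid * Wtr / len(tr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Z, u, alphas=alphas, tol=COEF_TOL * 1e-2,
                                     max_iter=200_000)
        # coefs: (p, n_alphas) in the order of `alphas` (decreasing)
        Zte = (X[te] - means) / sds
        preds = Zte @ coefs + ybar  # (n_te, n_alphas)
        wte = w[te]
        sq_err[f] = (wte[:, None] * (y[te][:, None] - preds) ** 2).sum(axis=0)
        fold_w[f] = wte.sum()
    mse_per_fold = sq_err / fold_w[:, None]
    mean_mse = sq_err.sum(axis=0) / fold_w.sum()
    se = mse_per_fold.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_mse))  # first minimum = largest lambda on ties
    return LambdaPath(lambdas=grid, cv_mse=mean_mse, cv_se=se,
                      lam_star=float(grid[best]), n_folds=folds, seed=seed)


def fit_cv_lasso(
    X,
    y,
    weights=None,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    stratify_on=None,
) -> Tuple[LinearFit, LambdaPath]:
    """CV-select the penalty, then refit on all rows at lam_star."""
    path = cv_select_lambda(X, y, weights, folds=folds, seed=seed,
                            standardize=standardize, stratify_on=stratify_on)
    fit = lasso_fit(X, y, weights, lam=path.lam_star, standardize=standardize)
    return fit, path
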