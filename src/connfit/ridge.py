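"""Ridge regression of activation on connectivity fingerprints.

The centerpiece is :class:`RidgeFingerprintRegressor`, a scikit-learn-style
estimator fitting

    min_w  Σ_v (y_v − x_v·w − b)² + λ‖w‖²          (intercept b unpenalized)

with the penalty λ selected by k-fold cross-validation over a deterministic
log-spaced grid. Because the intercept is unpenalized, the in-sample
coefficient of determination is guaranteed to lie in [0, 1].

Module-level functions (``fit_ridge``, ``optimize_lambda``,
``fit_region_domain``) are thin wrappers over the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted

from .config import RidgeFitSpec
from .connectivity import ConnectivityMatrix
from .exceptions import DataError
from .parcellation import Parcellation


@dataclass
class ModelFitResult:
    """Fitted ridge model for one (region, domain) pair."""

    region_id: int
    domain_id: int
    lambda_selected: float
    coefficients: np.ndarray
    intercept: float
    r_squared: float
    n_vertices: int
    cv_curve: np.ndarray | None = field(default=None, repr=False)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 − SSres/SStot.

    Undefined (raises) for constant ``y``.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("R^2 undefined: response has zero variance")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _solve_ridge(xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Solve (Xc'Xc + λI) w = Xc'yc on centered data."""
    k = xc.shape[1]
    if lam == 0.0:
        w, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        return w
    gram = xc.T @ xc + lam * np.eye(k)
    return scipy.linalg.solve(gram, xc.T @ yc, assume_a="pos")


def fit_ridge(
    X: np.ndarray, y: np.ndarray, lam: float, standardize: bool = False
) -> tuple[np.ndarray, float]:
    """Ridge coefficients and unpenalized intercept at a fixed penalty.

    Returns ``(coefficients, intercept)`` on the original data scale; with
    ``standardize`` the penalty is applied to unit-variance columns and the
    coefficients are mapped back.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in ridge inputs")
    if lam < 0:
        raise DataError("ridge penalty must be nonnegative")
    if X.shape[0] < 2:
        raise DataError("need at least 2 rows to fit")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    xc = X - x_mean
    yc = y - y_mean
    if standardize:
        scale = xc.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        w = _solve_ridge(xc / scale, yc, lam) / scale
    else:
        w = _solve_ridge(xc, yc, lam)
    intercept = float(y_mean - x_mean @ w)
    return w, intercept


class RidgeFingerprintRegressor(RegressorMixin, BaseEstimator):
    """Ridge regression with a cross-validated penalty on a log grid.

    Parameters
    ----------
    n_folds : int, default=5
        Cross-validation folds for penalty selection. If there are fewer
        than ``2 * n_folds`` samples the fold count drops to
        ``max(2, n_samples // 2)`` with a warning.
    max_evaluations : int, default=100
        Number of candidate penalties (grid points) evaluated.
    lambda_grid_bounds : (float, float), default=(1e-6, 1e4)
        Relative grid bounds; the evaluated grid is scaled by the mean
        diagonal of the centered Gram matrix ``Xc'Xc``.
    alpha : float or None, default=None
        Fixed penalty. When given, cross-validation is skipped.
    standardize : bool, default=False
        Penalize unit-variance columns instead of raw-scale columns.
    random_state : int, default=0
        Seed of the shuffled fold assignment.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    lambda_ : float
        Selected (or fixed) penalty.
    cv_curve_ : ndarray of shape (max_evaluations, 2)
        Columns (λ, mean out-of-fold squared error); ``None`` when ``alpha``
        was fixed.
    r_squared_ : float
        In-sample coefficient of determination on the training data.
    """

    def __init__(
        self,
        n_folds: int = 5,
        max_evaluations: int = 100,
        lambda_grid_bounds: tuple[float, float] = (1e-6, 1e4),
        alpha: float | None = None,
        standardize: bool = False,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.max_evaluations = max_evaluations
        self.lambda_grid_bounds = lambda_grid_bounds
        self.alpha = alpha
        self.standardize = standardize
        self.random_state = random_state

    # ---- internals ------------------------------------------------------

    def _grid(self, xc: np.ndarray) -> np.ndarray:
        scale = float(np.mean(np.sum(xc**2, axis=0)))
        if scale == 0.0:
            scale = 1.0
        low, high = self.lambda_grid_bounds
        return np.logspace(np.log10(low), np.log10(high), self.max_evaluations) * scale

    def _cv_select(self, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = X.shape[0]
        if n < 4:
            raise DataError(f"need at least 4 samples to cross-validate, got {n}")
        if np.ptp(y) == 0:
            raise DataError("response is constant; penalty selection undefined")
        n_folds = self.n_folds
        if n < 2 * n_folds:
            n_folds = max(2, n // 2)
            warnings.warn(
                f"only {n} samples: reducing CV folds to {n_folds}",
                RuntimeWarning,
                stacklevel=2,
            )
        grid = self._grid(X - X.mean(axis=0))
        sse = np.zeros(grid.shape[0])
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        for train, val in kf.split(X):
            xt, yt = X[train], y[train]
            xm, ym = xt.mean(axis=0), yt.mean()
            xtc = xt - xm
            if self.standardize:
                col = xtc.std(axis=0, ddof=0)
                col[col == 0] = 1.0
                xtc = xtc / col
            u, s, vt = np.linalg.svd(xtc, full_matrices=False)
            uty = u.T @ (yt - ym)
            xv = X[val] - xm
            if self.standardize:
                xv = xv / col
            xvv = xv @ vt.T
            for i, lam in enumerate(grid):
                shrink = s / (s**2 + lam)
                pred = xvv @ (shrink * uty) + ym
                sse[i] += float(np.sum((y[val] - pred) ** 2))
        cv_err = sse / n
        # tie-break toward the larger penalty
        best = np.flatnonzero(cv_err == cv_err.min())[-1]
        return float(grid[best]), np.column_stack([grid, cv_err])

    # ---- estimator API --------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeFingerprintRegressor":
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.shape[0] != X.shape[0]:
            raise DataError("X and y disagree on the number of samples")
        if not np.all(np.isfinite(y)):
            raise DataError("non-finite values in y")
        if self.alpha is not None:
            self.lambda_ = float(self.alpha)
            self.cv_curve_ = None
        else:
            self.lambda_, self.cv_curve_ = self._cv_select(X, y)
        self.coef_, self.intercept_ = fit_ridge(
            X, y, self.lambda_, standardize=self.standardize
        )
        self.n_features_in_ = X.shape[1]
        yhat = X @ self.coef_ + self.intercept_
        self.r_squared_ = r_squared(y, yhat) if np.ptp(y) > 0 else 0.0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_


def optimize_lambda(
    X: np.ndarray, y: np.ndarray, spec: RidgeFitSpec
) -> tuple[float, np.ndarray]:
    """Select the ridge penalty by seeded k-fold CV over a log-spaced grid.

    Returns ``(lambda_selected, cv_curve)`` where ``cv_curve`` holds all
    evaluated (λ, mean out-of-fold squared error) pairs. Exact ties in CV
    error resolve toward the larger penalty.
    """
    est = RidgeFingerprintRegressor(
        n_folds=spec.n_folds,
        max_evaluations=spec.max_evaluations,
        lambda_grid_bounds=spec.lambda_grid_bounds,
        standardize=spec.standardize,
        random_state=spec.seed,
    )
    X = check_array(np.asarray(X, dtype=np.float64), dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    return est._cv_select(X, y)


def fit_region_domain(
    conn: ConnectivityMatrix,
    activation: np.ndarray,
    parcellation: Parcellation,
    region_id: int,
    spec: RidgeFitSpec | None = None,
    domain_id: int = -1,
) -> ModelFitResult:
    """Fit one region's activation from its vertices' fingerprints.

    Restricts rows to the region's vertices, selects λ by CV, refits on all
    the region's vertices at the selected λ, and reports in-sample R².
    """
    spec = spec or RidgeFitSpec()
    meta = parcellation.region_meta.set_index("region_id")
    if region_id not in meta.index or not bool(meta.loc[region_id, "modeled"]):
        raise DataError(f"region {region_id} is not a modeled region")
    idx = parcellation.vertices_of(region_id)
    X = conn.values[idx]
    y = np.asarray(activation, dtype=np.float64)[idx]
    if np.ptp(y) == 0:
        raise DataError(f"degenerate (constant) activation in region {region_id}")
    est = RidgeFingerprintRegressor(
        n_folds=spec.n_folds,
        max_evaluations=spec.max_evaluations,
        lambda_grid_bounds=spec.lambda_grid_bounds,
        standardize=spec.standardize,
        random_state=spec.seed,
    ).fit(X, y)
    return ModelFitResult(
        region_id=int(region_id),
        domain_id=int(domain_id),
        lambda_selected=est.lambda_,
        coefficients=est.coef_,
        intercept=est.intercept_,
        r_squared=est.r_squared_,
        n_vertices=int(idx.size),
        cv_curve=est.cv_curve_,
    )
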