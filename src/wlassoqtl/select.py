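"""Sparse marker selection: weighted lasso, baselines and LRT/LOD scores.

The weighted lasso (wlasso) extends the lasso by weighting *observations*
according to how much their genotype vector was imputed.  With per-entry
certainty weights w_ij in [0, 1] it solves

    theta-hat_lambda = argmin_theta  sum_i  w_i(theta) (y_i - x_i' theta)^2
                                     + lambda ||theta||_1,
    w_i(theta) = sum_j w_ij |theta_j| / sum_j |theta_j|,

a circular definition resolved by iterative reweighting: start from the
ordinary lasso (all w_i = 1), alternate the weight update and a weighted
L1 fit until the squared Euclidean change of the weight vector drops
below a tolerance.  A RIL whose weights vanish on every active marker is
thereby eliminated from the regression, while fully observed RILs keep
weight one; with no imputation the method *is* the ordinary lasso.

lambda is selected by BIC(lambda) = RSS(lambda)/s^2 + df(lambda) ln(n)
with s^2 a lambda-free robust variance estimate and df the number of
nonzero coefficients.

Baselines: ordinary lasso, adaptive lasso (penalty weights
1/|theta_OLS|^gamma), and a multiple-regression scan over a grid of
per-marker t-test significance thresholds.  Per-marker evidence is
scored as an LRT on the log10 scale (LOD-like): (n/2) log10(RSS_without /
RSS_with) from two OLS fits.

The inner L1 solves go through scikit-learn's coordinate descent; the
weighted problem is reduced to a plain lasso by scaling rows with
sqrt(w_i) (sklearn's alpha equals lambda / (2 n)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "WlassoConfig",
    "WlassoFit",
    "MarkerScore",
    "default_lambda_grid",
    "wlasso_path",
    "bic_select",
    "lasso_baseline",
    "adaptive_lasso_baseline",
    "multiple_regression_scan",
    "marker_lrt_scores",
]


@dataclass
class WlassoConfig:
    lambda_grid: np.ndarray | None = None
    tol: float = 1e-8  # squared weight-change convergence tolerance
    max_iter: int = 50  # outer reweighting iterations
    inner_tol: float = 1e-7  # coordinate-descent tolerance

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or g.size == 0 or np.any(g <= 0):
                raise ValueError("lambda_grid must be positive")
            if g.size > 1 and not np.all(np.diff(g) < 0):
                raise ValueError("lambda_grid must be strictly descending")
            self.lambda_grid = g


@dataclass
class WlassoFit:
    lambda_grid: np.ndarray
    coef_path: np.ndarray  # n_lambda x p
    obs_weights: np.ndarray  # n_lambda x n, converged w_i per lambda
    weight_traces: list  # per lambda: list of w arrays (iteration x n)
    n_iter: np.ndarray  # outer iterations per lambda
    converged: np.ndarray  # bool per lambda
    bic: np.ndarray
    s2: float
    df_path: np.ndarray
    lambda_star: float = field(default=np.nan)
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass(frozen=True)
class MarkerScore:
    marker: str
    lrt_log10: float | None  # None = rank-deficient, not scorable
    model: str


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero solution) down
    three decades.  lambda_max = 2 max_j |x_j' y| for the objective
    ||y - X theta||^2 + lambda ||theta||_1."""
    lmax = 2.0 * np.max(np.abs(X.T @ y))
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax / 1000.0, n_points)


def _check_finite(X, y):
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")


def _sk_lasso(X, y, lam, n, tol, coef_init=None):
    """min ||y - X theta||^2 + lam ||theta||_1 via sklearn (alpha = lam/2n)."""
    model = Lasso(
        alpha=lam / (2.0 * n), fit_intercept=False, max_iter=100000, tol=tol
    )
    if coef_init is not None:
        model.warm_start = True
        model.coef_ = coef_init.copy()
    model.fit(X, y)
    return model.coef_.copy()


def _row_weights(W: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """w_i = sum_j w_ij |theta_j| / sum_j |theta_j|; all-zero theta -> 1."""
    a = np.abs(theta)
    denom = a.sum()
    if denom == 0.0:
        return np.ones(W.shape[0])
    return (W @ a) / denom


def wlasso_path(
    X: np.ndarray,
    y: np.ndarray,
    W: np.ndarray,
    cfg: WlassoConfig | None = None,
) -> WlassoFit:
    """Weighted-lasso coefficient path over a descending lambda grid.

    Each lambda starts from the ordinary-lasso solution (unit observation
    weights) and alternates the weight update with a weighted L1 fit until
    the squared change of the weight vector falls below ``cfg.tol``.
    """
    cfg = cfg or WlassoConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    _check_finite(X, y)
    if W.shape != X.shape:
        raise ValueError("weight matrix must match design shape")
    if np.any((W < 0) | (W > 1)):
        raise ValueError("weights must lie in [0, 1]")
    n, p = X.shape
    grid = cfg.lambda_grid if cfg.lambda_grid is not None else default_lambda_grid(X, y)

    # ordinary-lasso initialization for the whole path (warm-started)
    _, init_coefs, _ = lasso_path(
        X, y, alphas=grid / (2.0 * n), tol=cfg.inner_tol, max_iter=100000
    )
    init_coefs = init_coefs.T  # n_lambda x p

    coef_path = np.zeros((grid.size, p))
    obs_weights = np.zeros((grid.size, n))
    traces: list = []
    n_iter = np.zeros(grid.size, dtype=int)
    converged = np.zeros(grid.size, dtype=bool)

    def objective(lam, theta):
        w = _row_weights(W, theta)
        return float(w @ (y - X @ theta) ** 2 + lam * np.abs(theta).sum())

    for k, lam in enumerate(grid):
        theta = init_coefs[k].copy()
        w_cur = np.ones(n)
        w_prev2 = None
        trace = [w_cur.copy()]
        best_obj = objective(lam, theta)
        best = (theta.copy(), w_cur.copy())
        for it in range(cfg.max_iter):
            w_new = _row_weights(W, theta)
            trace.append(w_new.copy())
            if np.sum((w_new - w_cur) ** 2) < cfg.tol:
                w_cur = w_new
                converged[k] = True
                best = (theta, w_new)
                break
            if w_prev2 is not None and np.sum((w_new - w_prev2) ** 2) < cfg.tol:
                # 2-cycle: a marker flickers in/out of the active set at
                # this lambda; the fixed point does not exist, keep the
                # best iterate under the weighted objective
                break
            sw = np.sqrt(w_new)
            theta = _sk_lasso(X * sw[:, None], y * sw, lam, n, cfg.inner_tol, theta)
            obj = objective(lam, theta)
            if obj < best_obj:
                best_obj = obj
                best = (theta.copy(), w_new.copy())
            w_prev2 = w_cur
            w_cur = w_new
            n_iter[k] = it + 1
        coef_path[k], obs_weights[k] = best
        traces.append(trace)

    s2 = _robust_s2(X, y)
    rss = np.sum((y[None, :] - coef_path @ X.T) ** 2, axis=1)
    df_path = np.count_nonzero(coef_path, axis=1)
    bic = rss / s2 + df_path * np.log(n)
    fit = WlassoFit(
        lambda_grid=grid,
        coef_path=coef_path,
        obs_weights=obs_weights,
        weight_traces=traces,
        n_iter=n_iter,
        converged=converged,
        bic=bic,
        s2=s2,
        df_path=df_path,
    )
    star = int(np.argmin(bic))  # grid descending -> ties favor larger lambda
    fit.lambda_star = float(grid[star])
    fit.selected = np.flatnonzero(coef_path[star])
    return fit


def _robust_s2(X: np.ndarray, y: np.ndarray) -> float:
    """lambda-free variance scale for the BIC: full-OLS residual variance
    when p < n, else a MAD-based estimate of the response spread."""
    n, p = X.shape
    if p < n:
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = n - rank
        if dof > 0:
            return float(resid @ resid / dof)
    mad = np.median(np.abs(y - np.median(y)))
    return float((1.4826 * mad) ** 2) if mad > 0 else float(np.var(y) + 1e-12)


def bic_select(
    fit: WlassoFit, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Recompute BIC over the fitted path and return (lambda_star, selected).

    Ties break toward larger lambda (the sparser model).
    """
    n = len(y)
    rss = np.sum((y[None, :] - fit.coef_path @ X.T) ** 2, axis=1)
    bic = rss / fit.s2 + fit.df_path * np.log(n)
    star = int(np.argmin(bic))
    return float(fit.lambda_grid[star]), np.flatnonzero(fit.coef_path[star])


def lasso_baseline(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary lasso path: returns (lambda_grid, coef_path n_lambda x p)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n = X.shape[0]
    grid = lambda_grid if lambda_grid is not None else default_lambda_grid(X, y)
    _, coefs, _ = lasso_path(X, y, alphas=grid / (2.0 * n), tol=1e-7, max_iter=100000)
    return grid, coefs.T


def adaptive_lasso_baseline(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive lasso with penalty weights 1/|theta_OLS|^gamma.

    Requires p < n so the OLS estimate exists; a column with theta_OLS = 0
    receives an infinite penalty (coefficient pinned at zero).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n, p = X.shape
    if p >= n:
        raise ValueError(
            "adaptive lasso needs p < n for the OLS initial estimate; "
            "no ridge fallback is provided"
        )
    theta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    scale = np.abs(theta_ols) ** gamma  # = 1/penalty weight
    active = scale > 0
    Xs = X[:, active] * scale[active]
    grid = lambda_grid if lambda_grid is not None else default_lambda_grid(Xs, y)
    _, coefs, _ = lasso_path(Xs, y, alphas=grid / (2.0 * n), tol=1e-7, max_iter=100000)
    path = np.zeros((grid.size, p))
    path[:, active] = coefs.T * scale[active]
    return grid, path


def default_threshold_grid(n_steps: int = 67, step: float = 0.015) -> np.ndarray:
    """Significance sweep 0.015, 0.030, ... (67 steps, covering [0, 1])."""
    return step * np.arange(1, n_steps + 1)


def multiple_regression_scan(
    X: np.ndarray, y: np.ndarray, thresholds: np.ndarray | None = None
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Single full OLS fit; select markers with t-test p-value <= threshold.

    Returns (thresholds, selected index arrays per threshold, p-values).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(X, y)
    n, p = X.shape
    if p >= n:
        raise ValueError("multiple regression scan needs p < n")
    D = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("singular design in multiple regression scan")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = n - D.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals[1:]), dof)  # drop the intercept
    grid = thresholds if thresholds is not None else default_threshold_grid()
    selected = [np.flatnonzero(pvals <= s) for s in grid]
    return np.asarray(grid, dtype=float), selected, pvals


def _rss(D: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ coef
    return float(r @ r)


def marker_lrt_scores(
    X: np.ndarray,
    y: np.ndarray,
    marker_names: list[str],
    marker_set: np.ndarray | None = None,
    model: str = "selected_set",
) -> list[MarkerScore]:
    """LRT evidence per marker on the log10 (LOD) scale.

    For each marker j in the set: score = (n/2) log10(RSS without j /
    RSS with j) from two OLS fits (with intercept) on the marker set.
    Scores below 0.01 are reported as 0; an exactly-duplicated marker
    scores 0 because dropping it leaves the fit unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    idx = np.arange(X.shape[1]) if marker_set is None else np.asarray(marker_set)
    if idx.size == 0:
        raise ValueError("marker set is empty")
    Xs = X[:, idx]
    D_full = np.column_stack([np.ones(n), Xs])
    rss_full = _rss(D_full, y)
    scores: list[MarkerScore] = []
    for k, j in enumerate(idx):
        D_red = np.delete(D_full, k + 1, axis=1)
        rss_red = _rss(D_red, y)
        if rss_full <= 0:
            scores.append(MarkerScore(marker_names[j], None, model))
            continue
        val = max((n / 2.0) * np.log10(rss_red / rss_full), 0.0)
        if val < 0.01:
            val = 0.0
        scores.append(MarkerScore(marker_names[j], float(val), model))
    return scores
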