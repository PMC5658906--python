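"""LASSO / Elastic Net comparison arm with unpenalized confounders.

Solves, by cyclical coordinate descent with warm starts along a
decreasing lambda grid::

    min_b  (1/2n) ||y - b0 - Z b||^2
           + lambda * sum_j pf_j * (alpha |b_j| + (1 - alpha)/2 b_j^2)

``pf_j`` is a per-column penalty factor: exposure columns carry
``pf_j = 1`` while confounders carry ``pf_j = 0`` and are therefore
never shrunk or selected away.  ``alpha = 1`` is the LASSO,
``alpha = 0`` generalized ridge.  The penalization parameter is chosen
by k-fold cross-validation (minimum mean out-of-fold squared error),
and the variables selected at the chosen lambda are refit by ordinary
least squares together with all confounders to obtain unpenalized,
mutually adjusted estimates with standard intervals.

Exposure columns are expected pre-standardized (the preprocessing
module's job); no internal re-standardization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PenalizedFit",
    "make_lambda_grid",
    "elastic_net_path",
    "cross_validate",
    "select_and_refit",
    "penalized_analysis",
]


@dataclass
class PenalizedFit:
    """Path, selection, and refit results for one elastic-net analysis."""

    alpha: float
    lambda_grid: np.ndarray
    coef_path: np.ndarray  # (n_lambda, p)
    intercept_path: np.ndarray  # (n_lambda,)
    penalty_factors: np.ndarray
    columns: list[str]
    chosen_lambda: Optional[float] = None
    cv_table: Optional[pd.DataFrame] = None
    selected: Optional[list[str]] = None
    refit_estimates: Optional[pd.DataFrame] = None

    def coefs_at(self, lam: float) -> pd.Series:
        """Coefficients at the grid point closest to ``lam``."""
        k = int(np.argmin(np.abs(self.lambda_grid - lam)))
        return pd.Series(self.coef_path[k], index=self.columns)

    def selection_at(self, lam: float, tol: float = 0.0) -> list[str]:
        """Penalized columns with nonzero coefficient at ``lam``."""
        coefs = self.coefs_at(lam)
        return [
            c for c, b, pf in zip(self.columns, coefs, self.penalty_factors)
            if pf > 0 and abs(b) > tol
        ]


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _coordinate_descent(
    G: np.ndarray,
    c: np.ndarray,
    beta: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Solve one lambda by covariance-update coordinate descent.

    ``G = Z'Z/n`` and ``c = Z'y/n`` on centred data; ``beta`` is the
    warm start (updated in place and returned).
    """
    p = len(c)
    d = np.diag(G).copy()
    l1 = lam * alpha * pf
    l2 = lam * (1.0 - alpha) * pf
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if d[j] <= 0:
                continue
            z = c[j] - G[j] @ beta + d[j] * beta[j]
            new = _soft_threshold(z, l1[j]) / (d[j] + l2[j])
            delta = new - beta[j]
            if delta != 0.0:
                beta[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return beta
    return beta


def make_lambda_grid(
    Z: np.ndarray,
    y: np.ndarray,
    alpha: float,
    penalty_factors: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.001,
) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max to its small multiple.

    lambda_max is the smallest lambda at which every penalized
    coefficient is zero, computed after projecting out the unpenalized
    (confounder) columns; for near-ridge mixing the usual
    ``max(alpha, 0.001)`` guard keeps it finite.
    """
    pf = np.asarray(penalty_factors, float)
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    free = pf == 0
    r = yc
    if free.any():
        # residualize on the always-active confounders
        coef, *_ = np.linalg.lstsq(Zc[:, free], yc, rcond=None)
        r = yc - Zc[:, free] @ coef
    n = len(y)
    a_eff = max(alpha, 1e-3)
    with np.errstate(divide="ignore"):
        scores = np.abs(Zc.T @ r) / (n * a_eff * np.where(pf > 0, pf, np.inf))
    lam_max = float(np.max(scores[pf > 0])) if (pf > 0).any() else 1.0
    if lam_max <= 0:
        lam_max = 1.0
    # nudge above the exact entry threshold so every penalized
    # coefficient is exactly zero at the top of the path despite rounding
    lam_max *= 1.0 + 1e-6
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def elastic_net_path(
    Z: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    penalty_factors: Sequence[float],
    lambda_grid: Optional[np.ndarray] = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PenalizedFit:
    """Fit the full coefficient path over a decreasing lambda grid."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if isinstance(Z, pd.DataFrame):
        columns = list(Z.columns)
        Z = Z.to_numpy(float)
    else:
        Z = np.asarray(Z, float)
        columns = [f"x{j}" for j in range(Z.shape[1])]
    y = np.asarray(y, float)
    pf = np.asarray(penalty_factors, float)
    if pf.shape != (Z.shape[1],):
        raise ValueError("penalty_factors length must match columns")
    if np.any(pf < 0):
        raise ValueError("penalty factors must be >= 0")

    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Z, y, alpha, pf)
    else:
        lambda_grid = np.asarray(lambda_grid, float)
        if np.any(np.diff(lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        if np.any(lambda_grid < 0):
            raise ValueError("lambda grid must be non-negative")

    zbar = Z.mean(axis=0)
    ybar = float(y.mean())
    Zc = Z - zbar
    yc = y - ybar
    n = len(y)
    G = Zc.T @ Zc / n
    c = Zc.T @ yc / n

    p = Z.shape[1]
    coef_path = np.empty((len(lambda_grid), p))
    intercept_path = np.empty(len(lambda_grid))
    beta = np.zeros(p)
    for k, lam in enumerate(lambda_grid):
        beta = _coordinate_descent(G, c, beta, lam, alpha, pf, tol, max_iter)
        coef_path[k] = beta
        intercept_path[k] = ybar - zbar @ beta
    return PenalizedFit(
        alpha=alpha,
        lambda_grid=lambda_grid,
        coef_path=coef_path,
        intercept_path=intercept_path,
        penalty_factors=pf,
        columns=columns,
    )


def cross_validate(
    Z: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    penalty_factors: Sequence[float],
    k_folds: int = 10,
    seed: int = 0,
    lambda_grid: Optional[np.ndarray] = None,
) -> tuple[float, pd.DataFrame]:
    """Choose lambda by k-fold CV (minimum mean out-of-fold MSE rule).

    Fold assignment is deterministic given ``seed``.  Returns the chosen
    lambda and a table of per-lambda CV error (mean and SE).
    """
    from sklearn.model_selection import KFold

    if isinstance(Z, pd.DataFrame):
        Zarr = Z.to_numpy(float)
    else:
        Zarr = np.asarray(Z, float)
    y = np.asarray(y, float)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if len(y) < k_folds:
        raise ValueError(f"n={len(y)} smaller than k_folds={k_folds}")
    pf = np.asarray(penalty_factors, float)
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Zarr, y, alpha, pf)

    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((k_folds, len(lambda_grid)))
    for f, (tr, te) in enumerate(kf.split(Zarr)):
        fit = elastic_net_path(
            Zarr[tr], y[tr], alpha, pf, lambda_grid=lambda_grid
        )
        pred = Zarr[te] @ fit.coef_path.T + fit.intercept_path
        sq_err[f] = np.mean((pred - y[te][:, None]) ** 2, axis=0)
    mean_mse = sq_err.mean(axis=0)
    se_mse = sq_err.std(axis=0, ddof=1) / np.sqrt(k_folds)
    k_best = int(np.argmin(mean_mse))
    table = pd.DataFrame(
        {"lambda": lambda_grid, "cv_mse": mean_mse, "cv_se": se_mse}
    )
    return float(lambda_grid[k_best]), table


def select_and_refit(
    design: pd.DataFrame,
    y: np.ndarray,
    selected: Sequence[str],
    confounders: Sequence[str],
) -> pd.DataFrame:
    """Omnibus OLS on the selected exposures plus all confounders.

    Returns per-coefficient estimates with standard errors and 95%
    confidence intervals.  An empty selection yields the
    confounder-only model.
    """
    import statsmodels.api as sm

    cols = list(selected) + [c for c in confounders if c not in selected]
    X = design[cols].to_numpy(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad_idx = [piv[i] for i in range(len(diag))
                   if diag[i] < diag.max() * 1e-10]
        names = ["intercept"] + cols
        raise ValueError(
            f"collinear refit design; offending columns: "
            f"{[names[i] for i in sorted(bad_idx)]}"
        )
    res = sm.OLS(np.asarray(y, float), X).fit()
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "parameter": ["intercept"] + cols,
            "estimate": res.params,
            "se": res.bse,
            "ci95_lower": ci[:, 0],
            "ci95_upper": ci[:, 1],
        }
    )
    out["selected_exposure"] = out["parameter"].isin(list(selected))
    return out.reset_index(drop=True)


def penalized_analysis(
    matrix,
    alpha: float = 0.5,
    k_folds: int = 10,
    seed: int = 0,
) -> PenalizedFit:
    """Full comparison-arm analysis on an :class:`AnalysisMatrix`.

    Exposures are penalized; covariates, fixed chemicals, and the GA
    spline basis are unpenalized confounders.  ``alpha=1`` gives the
    LASSO, intermediate ``alpha`` the elastic net.
    """
    X = matrix.X
    conf = matrix.C.copy()
    if matrix.B is not None:
        for k in range(matrix.B.shape[1]):
            conf[f"ga_spline_{k + 1}"] = matrix.B[:, k]
    design = pd.concat([X, conf], axis=1)
    pf = np.concatenate([np.ones(X.shape[1]), np.zeros(conf.shape[1])])

    chosen, cv_table = cross_validate(
        design, matrix.y, alpha, pf, k_folds=k_folds, seed=seed
    )
    fit = elastic_net_path(design, matrix.y, alpha, pf)
    fit.chosen_lambda = chosen
    fit.cv_table = cv_table
    fit.selected = fit.selection_at(chosen)
    fit.refit_estimates = select_and_refit(
        design, matrix.y, fit.selected, list(conf.columns)
    )
    return fit
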