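"""Cross-validated LASSO selection of the network structure.

The fit minimises

    (1/2N) * sum_i (y_i - b0 - x_i' b)^2 + lambda * sum_j |b_j|

over a descending lambda path, with the intercept unpenalised.
Predictors are standardised (mean 0, sd 1) internally before the penalty
is applied — otherwise blocks on different scales (inputs vs squared
terms) face unequal shrinkage — and coefficients are reported back on
the original scale.

K-fold cross-validation (seeded shuffle of row indices) scores each
lambda by held-out mean squared prediction error ("deviance" for the
Gaussian model). Two canonical penalties are reported: ``lambda_min``,
the minimiser of mean CV deviance, and ``lambda_1se``, the largest
lambda whose mean deviance is within one standard error of that
minimum. The selected support is then refit by ordinary least squares,
which is what the downstream nested-model F/t tests operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import lasso_path

from .design import ColumnDescriptor, DesignMatrix

__all__ = ["SelectionResult", "fit_lasso_path", "select_model", "lambda_max"]

RULES = ("min_deviance", "one_se")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a cross-validated LASSO path fit for one seed region.

    ``coef_path`` holds original-scale coefficients for every lambda
    (columns follow ``lambda_path``), so the support at either rule can
    be re-derived without refitting.
    """

    lambda_path: np.ndarray
    cv_mean_deviance: np.ndarray
    cv_sd: np.ndarray  # standard error of the fold deviances
    lambda_min: float
    lambda_1se: float
    chosen_rule: str
    chosen_lambda: float
    support: tuple[ColumnDescriptor, ...]
    support_indices: tuple[int, ...]
    lasso_coefficients: np.ndarray  # on support, original scale
    lasso_intercept: float
    refit_coefficients: np.ndarray  # OLS on support, original scale
    refit_intercept: float
    coef_path: np.ndarray
    intercept_path: np.ndarray
    n_folds: int
    seed: int
    excluded_columns: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        """JSON-ready summary (the full coefficient path is omitted)."""
        return {
            "seed": self.seed,
            "n_folds": self.n_folds,
            "chosen_rule": self.chosen_rule,
            "chosen_lambda": self.chosen_lambda,
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "lambda_path": self.lambda_path.tolist(),
            "cv_mean_deviance": self.cv_mean_deviance.tolist(),
            "cv_sd": self.cv_sd.tolist(),
            "support": [str(c) for c in self.support],
            "lasso_intercept": self.lasso_intercept,
            "lasso_coefficients": self.lasso_coefficients.tolist(),
            "refit_intercept": self.refit_intercept,
            "refit_coefficients": self.refit_coefficients.tolist(),
            "excluded_columns": list(self.excluded_columns),
        }


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution on standardised data.

    From the subgradient condition of the objective: the zero vector is
    optimal iff lambda >= max_j |<x_j, y - ybar>| / N with x_j
    standardised.
    """
    xs, _, _ = _standardize(X)
    n = X.shape[0]
    return float(np.max(np.abs(xs.T @ (y - y.mean()))) / n)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _lasso_path_fit(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Original-scale coefficients and intercepts along a descending path.

    Solved by coordinate descent on standardised predictors and centred
    response (equivalent to an unpenalised intercept), warm-started down
    the path with a precomputed Gram matrix.
    """
    xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    gram = xs.T @ xs
    _, coefs_std, _ = lasso_path(
        xs, yc, alphas=lambdas, precompute=gram, max_iter=20_000, tol=tol
    )
    coefs = coefs_std / sd[:, None]
    intercepts = y.mean() - mu @ coefs
    return coefs, intercepts


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares intercept and coefficients (minimum-norm on ties)."""
    a = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(beta[0]), beta[1:]


def fit_lasso_path(
    dm: DesignMatrix,
    n_folds: int = 10,
    seed: int = 0,
    lambda_path: np.ndarray | None = None,
    rule: str = "min_deviance",
    path_length: int = 100,
    path_ratio: float = 1e-4,
    tol: float = 1e-7,
    cv_tol: float = 1e-5,
) -> SelectionResult:
    """Fit the full LASSO path with K-fold CV and select a model.

    The default path is ``path_length`` log-spaced values from the data's
    lambda_max down to ``lambda_max * path_ratio``. Fold membership comes
    from a seeded uniform shuffle of row indices, reproducible
    bit-for-bit for a given (data, n_folds, seed, path).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if dm.n_rows < n_folds:
        raise ValueError(f"{dm.n_rows} rows cannot be split into {n_folds} folds")
    X_full, y = dm.X, dm.y

    active = np.flatnonzero(np.ptp(X_full, axis=0) > 0)
    excluded = tuple(int(i) for i in range(dm.n_columns) if i not in set(active))
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant predictor column(s) from the fit",
            stacklevel=2,
        )
    X = X_full[:, active]

    if lambda_path is None:
        lam_hi = lambda_max(X, y)
        lambda_path = np.geomspace(lam_hi, lam_hi * path_ratio, path_length)
    else:
        lambda_path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]
        if np.any(lambda_path <= 0):
            raise ValueError("lambda path must be positive")

    rng = np.random.default_rng(seed)
    fold_of = np.empty(dm.n_rows, dtype=int)
    fold_of[rng.permutation(dm.n_rows)] = np.arange(dm.n_rows) % n_folds

    fold_dev = np.empty((n_folds, lambda_path.size))
    for k in range(n_folds):
        test = fold_of == k
        coefs, intercepts = _lasso_path_fit(X[~test], y[~test], lambda_path, tol=cv_tol)
        pred = X[test] @ coefs + intercepts  # (n_test, n_lambda)
        fold_dev[k] = np.mean((y[test, None] - pred) ** 2, axis=0)

    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mean))  # first index = largest lambda on ties
    lam_min = float(lambda_path[i_min])
    within = np.flatnonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])
    lam_1se = float(lambda_path[within.min()])  # path descends: first = largest

    coef_path_act, intercept_path = _lasso_path_fit(X, y, lambda_path, tol=tol)
    coef_path = np.zeros((dm.n_columns, lambda_path.size))
    coef_path[active] = coef_path_act

    sr = SelectionResult(
        lambda_path=lambda_path,
        cv_mean_deviance=cv_mean,
        cv_sd=cv_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        chosen_rule=rule,
        chosen_lambda=np.nan,
        support=(),
        support_indices=(),
        lasso_coefficients=np.empty(0),
        lasso_intercept=np.nan,
        refit_coefficients=np.empty(0),
        refit_intercept=np.nan,
        coef_path=coef_path,
        intercept_path=intercept_path,
        n_folds=n_folds,
        seed=seed,
        excluded_columns=excluded,
    )
    return select_model(sr, rule, dm)


def select_model(sr: SelectionResult, rule: str, dm: DesignMatrix) -> SelectionResult:
    """Fix the support at the lambda implied by ``rule`` and refit by OLS.

    ``min_deviance`` (the default) takes lambda_min; ``one_se`` takes the
    more regularised lambda_1se. An empty support yields an
    intercept-only refit at mean(y) — not an error.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    lam = sr.lambda_min if rule == "min_deviance" else sr.lambda_1se
    i = int(np.argmin(np.abs(sr.lambda_path - lam)))
    idx = tuple(int(j) for j in np.flatnonzero(sr.coef_path[:, i] != 0.0))
    support = tuple(dm.columns[j] for j in idx)
    lasso_coef = sr.coef_path[list(idx), i] if idx else np.empty(0)
    refit_b0, refit_b = _ols(dm.X[:, list(idx)] if idx else np.empty((dm.n_rows, 0)),
                             dm.y)
    return replace(
        sr,
        chosen_rule=rule,
        chosen_lambda=float(lam),
        support=support,
        support_indices=idx,
        lasso_coefficients=lasso_coef,
        lasso_intercept=float(sr.intercept_path[i]),
        refit_coefficients=refit_b,
        refit_intercept=refit_b0,
    )
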