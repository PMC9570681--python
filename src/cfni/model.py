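"""Weight learning and the three-variable 0-100 nutrition index.

Carts' HEI totals are regressed on two of the three tier percentages
(%green and %red; %yellow is their complement) with three estimators:

* ``model1_ridge_ic`` — ridge regression with the penalty chosen by an
  information criterion (BIC by default) over a lambda grid;
* ``model2_ridge_cv`` — ridge regression with the penalty chosen by
  k-fold cross-validated held-out squared error;
* ``model3_ols``      — ordinary least squares.

Ridge is solved in closed form on centered, sample-SD-standardized
predictors with an unpenalized intercept; coefficients are reported back
on the raw percentage scale, so lambda = 0 reproduces OLS exactly.

A fitted model ``HEI ~ c + bG*G + bR*R`` is turned into a weighted sum of
all three tier percentages using G + Y + R = 100:

    c + bG*G + bR*R = (c/100 + bG)*G + (c/100)*Y + (c/100 + bR)*R

The three weights are then affinely rescaled so that the weighted sum maps
the composition simplex onto [0, 100]: offset = 100 * min(weight),
scale = 100 * (max - min).  A 100%-green cart scores 100 and a 100%-red
cart scores 0 whenever green carries the largest and red the smallest
weight.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    CfniError,
    DegenerateFormulaError,
    PartitionError,
    SelectionError,
    SingularDesignError,
    ValidationError,
)
from .types import FittedLinearModel, IndexFormula, TierSummary

#: default penalty grid: 101 log-spaced points
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 4, 101))

_METHODS = ("model1_ridge_ic", "model2_ridge_cv", "model3_ols")


def _design(summaries, hei) -> tuple[np.ndarray, np.ndarray]:
    """Align tier summaries and HEI scores on cart_id; return (X, y).

    Accepts DataFrames with (cart_id, pct_green, pct_red) / (cart_id, total)
    columns, or sequences of TierSummary / HEIScore.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame(
            {
                "cart_id": [s.cart_id for s in summaries],
                "pct_green": [s.pct_green for s in summaries],
                "pct_red": [s.pct_red for s in summaries],
            }
        )
    if not isinstance(hei, pd.DataFrame):
        hei = pd.DataFrame(
            {"cart_id": [h.cart_id for h in hei], "total": [h.total for h in hei]}
        )
    merged = summaries[["cart_id", "pct_green", "pct_red"]].merge(
        hei[["cart_id", "total"]], on="cart_id", validate="1:1"
    )
    if len(merged) < 3:
        raise ValidationError(f"need >= 3 matched carts, got {len(merged)}")
    X = merged[["pct_green", "pct_red"]].to_numpy(dtype=float)
    y = merged["total"].to_numpy(dtype=float)
    return X, y


def fit_ols(summaries, hei) -> FittedLinearModel:
    """OLS fit of HEI on (%green, %red) with intercept, by normal equations."""
    X, y = _design(summaries, hei)
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < A.shape[1]:
        raise SingularDesignError("design matrix is rank deficient (constant predictor?)")
    beta = np.linalg.solve(gram, A.T @ y)
    return FittedLinearModel(
        method="model3_ols",
        coef_green=float(beta[1]),
        coef_red=float(beta[2]),
        constant=float(beta[0]),
        penalty=0.0,
    )


def _ridge_beta(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Closed-form ridge on centered, sample-SD-standardized predictors.

    Returns (intercept, raw-scale coefficients). The intercept is not
    penalized; lambda = 0 is exactly OLS.
    """
    xm = X.mean(axis=0)
    ym = y.mean()
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise SingularDesignError("a predictor is constant; ridge standardization undefined")
    Z = (X - xm) / sd
    yc = y - ym
    p = Z.shape[1]
    beta_z = np.linalg.solve(Z.T @ Z + lam * np.eye(p), Z.T @ yc)
    beta = beta_z / sd
    intercept = ym - xm @ beta
    return float(intercept), beta


def fit_ridge(summaries, hei, penalty: float, method: str = "model2_ridge_cv") -> FittedLinearModel:
    """Ridge fit at a fixed penalty lambda >= 0."""
    if penalty < 0:
        raise ValidationError(f"penalty must be >= 0, got {penalty}")
    X, y = _design(summaries, hei)
    intercept, beta = _ridge_beta(X, y, penalty)
    return FittedLinearModel(
        method=method,
        coef_green=float(beta[0]),
        coef_red=float(beta[1]),
        constant=intercept,
        penalty=float(penalty),
    )


def effective_df(X: np.ndarray, lam: float) -> float:
    """Trace of the ridge hat matrix on standardized predictors, plus one
    for the unpenalized intercept: df = sum d_i^2 / (d_i^2 + lambda) + 1."""
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / sd
    d2 = np.linalg.svd(Z, compute_uv=False) ** 2
    return float(np.sum(d2 / (d2 + lam)) + 1.0)


def select_penalty_ic(
    summaries, hei, lambda_grid=DEFAULT_LAMBDA_GRID, criterion: str = "bic"
) -> FittedLinearModel:
    """Ridge with the penalty minimizing an information criterion.

    criterion(lambda) = n * log(RSS/n) + w * df_eff, with w = 2 for AIC and
    w = log(n) for BIC, and df_eff the ridge hat-matrix trace.  Ties are
    broken toward larger lambda (more shrinkage).
    """
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise SelectionError("lambda grid is empty")
    if criterion not in ("aic", "bic"):
        raise ValidationError(f"criterion must be 'aic' or 'bic', got '{criterion}'")
    X, y = _design(summaries, hei)
    n = len(y)
    w = 2.0 if criterion == "aic" else float(np.log(n))
    crits = np.empty(grid.size)
    for i, lam in enumerate(grid):
        intercept, beta = _ridge_beta(X, y, lam)
        rss = float(np.sum((y - intercept - X @ beta) ** 2))
        df = effective_df(X, lam)
        crits[i] = n * np.log(max(rss / n, 1e-300)) + w * df
    if not np.any(np.isfinite(crits)):
        raise SelectionError("no finite criterion value on the lambda grid")
    # ties toward larger lambda: scan descending-lambda order for the min
    order = np.argsort(-grid, kind="stable")
    best = order[np.argmin(crits[order])]
    model = fit_ridge(summaries, hei, float(grid[best]), method="model1_ridge_ic")
    return FittedLinearModel(
        method="model1_ridge_ic",
        coef_green=model.coef_green,
        coef_red=model.coef_red,
        constant=model.constant,
        penalty=model.penalty,
        diagnostics={"criterion": criterion, "lambda_grid": grid.tolist(),
                     "criterion_values": crits.tolist()},
    )


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition into k folds with sizes differing by <= 1;
    the remainder goes to the lowest-index folds."""
    if k < 2:
        raise PartitionError(f"need k >= 2 folds, got {k}")
    if n < k:
        raise PartitionError(f"cannot split n={n} into k={k} folds")
    perm = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, k)]


def select_penalty_cv(
    summaries, hei, lambda_grid=DEFAULT_LAMBDA_GRID, folds: int = 10, seed: int = 0
) -> FittedLinearModel:
    """Ridge with the penalty minimizing seeded k-fold held-out MSE.

    The final model is refit on all data at the selected lambda; ties are
    broken toward larger lambda.
    """
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise SelectionError("lambda grid is empty")
    X, y = _design(summaries, hei)
    n = len(y)
    rng = np.random.default_rng(seed)
    idx_folds = _fold_indices(n, folds, rng)
    mse = np.zeros(grid.size)
    for f in idx_folds:
        train = np.setdiff1d(np.arange(n), f)
        for i, lam in enumerate(grid):
            intercept, beta = _ridge_beta(X[train], y[train], lam)
            resid = y[f] - intercept - X[f] @ beta
            mse[i] += float(np.mean(resid**2))
    mse /= len(idx_folds)
    order = np.argsort(-grid, kind="stable")
    best = order[np.argmin(mse[order])]
    model = fit_ridge(summaries, hei, float(grid[best]), method="model2_ridge_cv")
    return FittedLinearModel(
        method="model2_ridge_cv",
        coef_green=model.coef_green,
        coef_red=model.coef_red,
        constant=model.constant,
        penalty=model.penalty,
        diagnostics={"folds": folds, "seed": seed, "lambda_grid": grid.tolist(),
                     "cv_mse": mse.tolist()},
    )


def fit_model(summaries, hei, method: str, *, lambda_grid=DEFAULT_LAMBDA_GRID,
              criterion: str = "bic", inner_folds: int = 10, seed: int = 0) -> FittedLinearModel:
    """Dispatch to the estimator named by ``method``."""
    if method in ("model1", "model1_ridge_ic"):
        return select_penalty_ic(summaries, hei, lambda_grid, criterion)
    if method in ("model2", "model2_ridge_cv"):
        return select_penalty_cv(summaries, hei, lambda_grid, inner_folds, seed)
    if method in ("model3", "model3_ols"):
        return fit_ols(summaries, hei)
    raise ValidationError(f"unknown method '{method}'; expected one of {_METHODS}")


def to_index_formula(model: FittedLinearModel) -> IndexFormula:
    """Rewrite a fitted two-predictor model as a rescaled three-weight index.

    Uses the simplex identity G + Y + R = 100 to distribute the constant
    over the three tiers, then rescales by the weighted sum's theoretical
    extremes over the simplex so scores span exactly [0, 100].
    """
    wg = model.constant / 100.0 + model.coef_green
    wy = model.constant / 100.0
    wr = model.constant / 100.0 + model.coef_red
    lo, hi = min(wg, wy, wr), max(wg, wy, wr)
    if hi == lo:
        raise DegenerateFormulaError("all tier weights equal; 0-100 rescaling undefined")
    return IndexFormula(
        coef_green_3v=wg,
        coef_yellow_3v=wy,
        coef_red_3v=wr,
        offset=100.0 * lo,
        scale=100.0 * (hi - lo),
    )


def cfni_score(formula: IndexFormula, summary) -> float:
    """Index value of one cart: the rescaled weighted tier sum, in [0, 100]
    for any composition on the simplex.

    ``summary`` may be a TierSummary or any object/mapping with pct_green,
    pct_yellow, pct_red summing to 100.
    """
    if isinstance(summary, dict):
        g, yv, r = summary["pct_green"], summary["pct_yellow"], summary["pct_red"]
    else:
        g, yv, r = summary.pct_green, summary.pct_yellow, summary.pct_red
    if abs(g + yv + r - 100.0) > 1e-6:
        raise ValidationError(f"tier percentages must sum to 100, got {g + yv + r}")
    s = formula.coef_green_3v * g + formula.coef_yellow_3v * yv + formula.coef_red_3v * r
    return (s - formula.offset) / formula.scale * 100.0


def cfni_scores(formula: IndexFormula, summaries: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`cfni_score` over a summaries DataFrame."""
    g = summaries["pct_green"].to_numpy(dtype=float)
    yv = summaries["pct_yellow"].to_numpy(dtype=float)
    r = summaries["pct_red"].to_numpy(dtype=float)
    if np.any(np.abs(g + yv + r - 100.0) > 1e-6):
        raise ValidationError("tier percentages must sum to 100 for every cart")
    s = formula.coef_green_3v * g + formula.coef_yellow_3v * yv + formula.coef_red_3v * r
    return (s - formula.offset) / formula.scale * 100.0
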