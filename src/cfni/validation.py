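"""Validation machinery: correlations, quintile profiles, and the 5-fold
cross-validated correlation between the index and HEI.

The cross-validated correlation answers the question the index exists for:
how well would the cheap tier-based score track the expensive HEI on carts
it was not fitted to?  Each fold holds out ~1/k of the carts, fits the
chosen model on the rest, builds the 0-100 index formula from the fit,
scores the held-out carts, and records the Pearson correlation between the
held-out index and held-out HEI.  Because the index is an affine rescaling
of predicted HEI, every fold correlation equals the correlation of the
fold's predicted HEI with observed HEI.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, PartitionError, ValidationError
from .model import _fold_indices, cfni_scores, fit_model, to_index_formula
from .types import CVResult, QuintileProfile

TIER_COLUMNS = ("pct_green", "pct_yellow", "pct_red")


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value from the
    t transform with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 observations, got {x.size}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise AnalysisError("correlation undefined: an input has zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def assign_quintiles(scores) -> np.ndarray:
    """Rank-based quintile labels 1-5 (1 = lowest score).

    Stable sort, ties resolved by input order; group sizes as equal as
    possible with remainders assigned to the lowest-index quintiles
    (n = 503 gives sizes 101, 101, 101, 100, 100).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 5:
        raise PartitionError(f"need >= 5 observations for quintiles, got {n}")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return labels


def quintile_profile(summaries: pd.DataFrame, labels) -> QuintileProfile:
    """Mean tier composition per HEI quintile, with linear trend tests.

    The trend test regresses each tier percentage on the quintile index
    treated as numeric 1-5 and reports the OLS slope with its two-sided
    t-test p-value (unadjusted).
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(summaries):
        raise ValidationError("labels must align with summaries")
    present = set(np.unique(labels))
    if present != {1, 2, 3, 4, 5}:
        raise PartitionError(f"expected quintiles 1-5, got {sorted(present)}")
    means: dict[int, dict[str, float]] = {}
    for q in range(1, 6):
        mask = labels == q
        row: dict[str, float] = {"count": int(mask.sum())}
        for col in TIER_COLUMNS:
            row[col] = float(summaries.loc[mask, col].mean())
        means[q] = row
    trends: dict[str, tuple[float, float]] = {}
    for col in TIER_COLUMNS:
        y = summaries[col].to_numpy(dtype=float)
        if np.var(y) == 0:  # flat response: zero slope, no evidence of trend
            trends[col] = (0.0, 1.0)
            continue
        res = stats.linregress(labels.astype(float), y)
        trends[col] = (float(res.slope), float(res.pvalue))
    return QuintileProfile(means=means, trends=trends)


def kfold_cv_correlation(
    summaries: pd.DataFrame,
    hei: pd.DataFrame,
    method: str = "model1_ridge_ic",
    k: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Mean held-out Pearson correlation between index and HEI over a
    seeded k-fold split.

    For each fold: fit the model on the other k-1 folds, transform the fit
    into an index formula, score the held-out carts, and correlate the
    held-out index with held-out HEI.  Reports the k fold correlations,
    their mean, and their sample SD (n-1 denominator).
    """
    merged = summaries.merge(hei[["cart_id", "total"]], on="cart_id", validate="1:1")
    n = len(merged)
    if n < 2 * k:
        raise PartitionError(f"need n >= 2k carts for {k}-fold CV, got n={n}")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    fold_rs, fold_sizes = [], []
    for f in folds:
        test = merged.iloc[f]
        train = merged.drop(merged.index[f])
        model = fit_model(train, train[["cart_id", "total"]], method, seed=seed, **fit_kwargs)
        formula = to_index_formula(model)
        idx_scores = cfni_scores(formula, test)
        heldout_hei = test["total"].to_numpy(dtype=float)
        if np.var(idx_scores) == 0 or np.var(heldout_hei) == 0:
            raise AnalysisError("held-out fold has zero variance; CV correlation undefined")
        r = float(np.corrcoef(idx_scores, heldout_hei)[0, 1])
        fold_rs.append(r)
        fold_sizes.append(int(f.size))
    mean_r = float(np.mean(fold_rs))
    sd_r = float(np.std(fold_rs, ddof=1))
    return CVResult(
        fold_sizes=tuple(fold_sizes),
        fold_correlations=tuple(fold_rs),
        mean_r=mean_r,
        sd_r=sd_r,
        method=method,
        seed=seed,
    )


def correlation_table(summaries: pd.DataFrame, hei: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of HEI with each tier percentage."""
    merged = summaries.merge(hei[["cart_id", "total"]], on="cart_id", validate="1:1")
    rows = []
    for col in TIER_COLUMNS:
        r, p = pearson_r(merged[col], merged["total"])
        rows.append({"variable": col, "r": r, "p": p})
    return pd.DataFrame(rows)
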