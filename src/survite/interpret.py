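"""Downstream interpretation of estimated individual effects.

Given per-patient effect estimates, a lasso regression of the effect on the
(standardized) baseline covariates ranks covariates by absolute coefficient;
binned five-number summaries of the effect against a covariate provide the
data behind the usual box-plot displays.

The lasso objective is ``(1/2N) sum_i (dY_i - w0 - x_i' w)^2 + iota * |w|_1``
with an unpenalized intercept, solved by cyclic coordinate descent with
soft-thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = ["ImportanceResult", "fit_ite_lasso", "select_iota",
           "rank_covariates", "binned_ite_summary"]


@dataclass
class ImportanceResult:
    intercept: float
    coefficients: np.ndarray
    penalty: float
    feature_names: list[str]
    ranked_covariates: list[str]


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def fit_ite_lasso(est_ite, X, iota: float,
                  feature_names: list[str] | None = None,
                  standardize: bool = True, tol: float = 1e-8,
                  max_iter: int = 100_000) -> ImportanceResult:
    """Cyclic coordinate descent for the lasso of effects on covariates.

    Covariates are standardized internally by default so the absolute
    coefficients are comparable for ranking.  Convergence when the largest
    coefficient change in a sweep is below ``tol``.
    """
    if iota < 0:
        raise ValueError("penalty iota must be nonnegative")
    y = np.asarray(est_ite, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match est_ite length")
    n, m = X.shape
    names = list(feature_names) if feature_names is not None else \
        [f"x{j}" for j in range(m)]
    if standardize:
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        X = (X - loc) / scale
    col_sq = (X ** 2).mean(axis=0)         # (1/N) sum x_ij^2
    w = np.zeros(m)
    w0 = float(y.mean())
    resid = y - w0 - X @ w
    for _ in range(max_iter):
        max_change = 0.0
        new_w0 = w0 + resid.mean()
        resid -= new_w0 - w0
        max_change = abs(new_w0 - w0)
        w0 = new_w0
        for j in range(m):
            if col_sq[j] == 0:
                continue
            rho = (X[:, j] @ resid) / n + col_sq[j] * w[j]
            new_wj = _soft(rho, iota) / col_sq[j]
            if new_wj != w[j]:
                resid -= X[:, j] * (new_wj - w[j])
                max_change = max(max_change, abs(new_wj - w[j]))
                w[j] = new_wj
        if max_change < tol:
            break
    order = sorted(range(m), key=lambda j: (-abs(w[j]), j))
    return ImportanceResult(intercept=w0, coefficients=w, penalty=iota,
                            feature_names=names,
                            ranked_covariates=[names[j] for j in order])


def lasso_objective(est_ite, X, w0: float, w, iota: float,
                    standardize: bool = True) -> float:
    """The value being minimized; exposed for verification."""
    y = np.asarray(est_ite, dtype=float)
    X = np.asarray(X, dtype=float)
    if standardize:
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        X = (X - loc) / scale
    resid = y - w0 - X @ np.asarray(w, dtype=float)
    return float((resid ** 2).sum() / (2 * y.size)
                 + iota * np.abs(w).sum())


def select_iota(est_ite, X, grid, k_folds: int = 5, seed: int = 0) -> float:
    """K-fold cross-validated penalty selection; ties go to the larger
    (sparser) penalty."""
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(est_ite, dtype=float)
    X = np.asarray(X, dtype=float)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(grid))
    for tr, te in kf.split(X):
        # standardize inside the fold to avoid leakage
        loc = X[tr].mean(axis=0)
        scale = X[tr].std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        Xtr = (X[tr] - loc) / scale
        Xte = (X[te] - loc) / scale
        for gi, iota in enumerate(grid):
            fit = fit_ite_lasso(y[tr], Xtr, iota, standardize=False)
            pred = fit.intercept + Xte @ fit.coefficients
            errors[gi] += float(np.mean((y[te] - pred) ** 2))
    best = errors.min()
    candidates = [g for g, e in zip(grid, errors) if e <= best + 1e-12]
    return max(candidates)


def rank_covariates(result: ImportanceResult, k: int) -> list[str]:
    """Top-k covariate names by absolute coefficient (ties by index)."""
    m = len(result.coefficients)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")
    return result.ranked_covariates[:k]


def binned_ite_summary(est_ite, covariate_values, bins) -> pd.DataFrame:
    """Per-bin five-number summary (count, min, q1, median, q3, max).

    ``bins`` is either a monotone array of edges (right-closed last bin) or a
    list of category values for a discrete covariate.  Quantiles use the
    linear-interpolation convention.  Empty bins yield count 0 and missing
    summaries.
    """
    y = np.asarray(est_ite, dtype=float)
    x = np.asarray(covariate_values, dtype=float)
    if y.shape != x.shape:
        raise ValueError("est_ite and covariate_values must align")
    rows = []
    edges = np.asarray(bins, dtype=float)
    categorical = len(edges) == len(np.unique(edges)) and np.all(
        np.isin(x, edges))
    if categorical:
        groups = [(f"{v:g}", x == v) for v in np.sort(np.unique(edges))]
    else:
        if np.any(x < edges[0]) or np.any(x > edges[-1]):
            raise ValueError("bin edges must cover the observed range")
        which = np.clip(np.digitize(x, edges, right=False) - 1, 0,
                        len(edges) - 2)
        groups = [(f"[{edges[i]:g}, {edges[i + 1]:g}"
                   + ("]" if i == len(edges) - 2 else ")"),
                   which == i) for i in range(len(edges) - 1)]
    for label, mask in groups:
        vals = y[mask]
        if vals.size == 0:
            rows.append({"bin": label, "count": 0, "min": np.nan,
                         "q1": np.nan, "median": np.nan, "q3": np.nan,
                         "max": np.nan})
        else:
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({"bin": label, "count": int(vals.size),
                         "min": float(vals.min()), "q1": float(q1),
                         "median": float(med), "q3": float(q3),
                         "max": float(vals.max())})
    return pd.DataFrame(rows)
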