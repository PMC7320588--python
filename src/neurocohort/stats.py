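"""Inferential procedures for the baseline analyses.

Covers ordinary least squares with coefficient t-tests, leave-one-out
cross-validated (LOOCV) bias-corrected RMSE, exhaustive predictor-subset
model selection, Spearman and partial correlation, residualization,
median-split grouping, pooled two-sample t-tests and Holm-Bonferroni
step-down correction.

The LOOCV residuals use the exact hat-matrix identity for linear models,
e_(i) = e_i / (1 - h_ii), which is algebraically identical to refitting
with observation i held out.  The "bias-corrected" RMSE reported for model
selection is the standard deviation of the LOOCV residuals, i.e.
sqrt(MSE - bias^2) with bias the mean LOOCV residual; the plain LOOCV RMSE
is carried alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, SingularDesignError, ValidationError

__all__ = [
    "FitResult",
    "ModelComparison",
    "CorrelationResult",
    "AdjustedTests",
    "fit_ols",
    "loocv_residuals",
    "loocv_rmse",
    "select_model",
    "spearman",
    "partial_correlation",
    "residualize",
    "median_split",
    "two_sample_t",
    "holm_bonferroni",
]

_RCOND = 1e-10


@dataclass
class FitResult:
    """OLS fit with classical standard errors (intercept first)."""

    predictors: tuple  # names, without the intercept
    params: np.ndarray  # length p + 1, intercept first
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    df_resid: int


@dataclass
class ModelComparison:
    """Exhaustive subset comparison ranked by bias-corrected LOOCV RMSE."""

    table: pd.DataFrame  # columns: predictors, k, loocv_rmse_bc, loocv_rmse
    selected: tuple  # predictor names of the winning subset
    criterion: float  # its bias-corrected LOOCV RMSE
    fit: FitResult  # full-data refit of the selected subset


@dataclass
class CorrelationResult:
    method: str  # "spearman" | "partial_pearson"
    estimate: float
    pvalue: float
    n: int
    covariates: tuple = ()


@dataclass
class AdjustedTests:
    """Holm step-down adjusted p-values for one comparison family."""

    pvalues_raw: np.ndarray
    pvalues_adjusted: np.ndarray
    reject: np.ndarray
    alpha: float
    family: str = ""


def _design(X, names=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(p))
    full = np.column_stack([np.ones(n), X])
    return full, tuple(names), n, p


def fit_ols(y, X, names: Optional[Sequence[str]] = None) -> FitResult:
    """Least squares of y on X with an intercept; classical t-tests.

    Raises :class:`SingularDesignError` on rank deficiency and
    :class:`ValidationError` when n <= p + 1.
    """
    y = np.asarray(y, dtype=float)
    A, names, n, p = _design(X, names)
    if n <= p + 1:
        raise ValidationError(f"need n > p + 1 observations (n={n}, p={p})")
    q, r = np.linalg.qr(A)
    if np.abs(np.diag(r)).min() <= _RCOND * np.abs(np.diag(r)).max():
        raise SingularDesignError("design matrix is rank deficient")
    beta = np.linalg.solve(r, q.T @ y)
    fitted = A @ beta
    resid = y - fitted
    df = n - p - 1
    sigma2 = resid @ resid / df
    rinv = np.linalg.solve(r, np.eye(p + 1))
    cov = sigma2 * (rinv @ rinv.T)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2 * sps.t.sf(np.abs(tvals), df)
    return FitResult(
        predictors=names,
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        residuals=resid,
        fitted=fitted,
        n=n,
        df_resid=df,
    )


def loocv_residuals(y, X) -> np.ndarray:
    """Leave-one-out prediction residuals e_i = y_i - yhat_(i).

    Computed via the hat-matrix identity e_i / (1 - h_ii); a leverage of 1
    means the leave-one-out fit is singular and raises, naming the index.
    """
    y = np.asarray(y, dtype=float)
    A, _, n, p = _design(X)
    if n <= p + 2:
        raise ValidationError(f"LOOCV needs n > p + 2 (n={n}, p={p})")
    fit = fit_ols(y, X)
    q, _ = np.linalg.qr(A)
    h = (q**2).sum(axis=1)
    near_one = h > 1 - 1e-10
    if near_one.any():
        i = int(np.argmax(near_one))
        raise SingularDesignError(f"leave-one-out fit singular when dropping index {i}")
    return fit.residuals / (1 - h)


def loocv_rmse(y, X, bias_corrected: bool = True) -> float:
    """LOOCV root-mean-square error; by default with the mean bias removed.

    bias-corrected: sqrt(mean(e^2) - mean(e)^2), the SD of the LOOCV
    residuals; plain: sqrt(mean(e^2)).
    """
    e = loocv_residuals(y, X)
    mse = float(np.mean(e**2))
    if not bias_corrected:
        return float(np.sqrt(mse))
    return float(np.sqrt(mse - np.mean(e) ** 2))


def select_model(y, candidates: pd.DataFrame) -> ModelComparison:
    """Score every nonempty predictor subset by bias-corrected LOOCV RMSE.

    ``candidates`` is a frame of named predictor columns (1 <= p <= 12).
    Ties break toward the smaller subset, then lexicographic name order.
    The winning subset is refit on the full data.
    """
    names = list(candidates.columns)
    p = len(names)
    if not 1 <= p <= 12:
        raise ValidationError(f"select_model supports 1..12 candidates, got {p}")
    y = np.asarray(y, dtype=float)
    rows = []
    for k in range(1, p + 1):
        for subset in combinations(sorted(names), k):
            X = candidates.loc[:, list(subset)].to_numpy(dtype=float)
            e = loocv_residuals(y, X)
            mse = float(np.mean(e**2))
            bc = float(np.sqrt(mse - np.mean(e) ** 2))
            plain = float(np.sqrt(mse))
            rows.append({"predictors": subset, "k": k, "loocv_rmse_bc": bc, "loocv_rmse": plain})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["loocv_rmse_bc", "k", "predictors"], kind="mergesort"
    ).reset_index(drop=True)
    selected = tuple(order.loc[0, "predictors"])
    criterion = float(order.loc[0, "loocv_rmse_bc"])
    fit = fit_ols(y, candidates.loc[:, list(selected)].to_numpy(dtype=float), names=selected)
    return ModelComparison(table=order, selected=selected, criterion=criterion, fit=fit)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties; p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("spearman undefined for constant input")
    r, p = sps.spearmanr(x, y)
    if not np.isfinite(r):
        raise DegenerateDataError("spearman correlation undefined (zero rank variance)")
    return CorrelationResult(method="spearman", estimate=float(r), pvalue=float(p), n=x.size)


def residualize(y, covariates) -> np.ndarray:
    """Residuals of y after OLS on the covariates (with intercept).

    The result is mean zero and orthogonal to every covariate column.
    """
    return fit_ols(y, covariates).residuals


def partial_correlation(x, y, covariates) -> CorrelationResult:
    """Pearson correlation of x and y after partialling out covariates.

    Both variables are residualized on the covariates (with intercept);
    the p-value uses t = r sqrt((n - q - 2)/(1 - r^2)) on n - q - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    names = tuple(f"c{j + 1}" for j in range(cov.shape[1]))
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
    n, q = cov.shape
    if n <= q + 2:
        raise ValidationError(f"partial correlation needs n > q + 2 (n={n}, q={q})")
    rx = residualize(x, cov)
    ry = residualize(y, cov)
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx <= _RCOND * max(1.0, np.abs(x).max()) or sy <= _RCOND * max(1.0, np.abs(y).max()):
        raise DegenerateDataError(
            "partial correlation undefined: a variable is fully explained by the covariates"
        )
    r = float((rx @ ry) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - q - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        method="partial_pearson", estimate=r, pvalue=p, n=n, covariates=names
    )


def median_split(scores) -> pd.DataFrame:
    """Split subjects at the mid-rank median: low (<= median) vs high (> median).

    Returns a frame with the input ``score`` and a ``group`` label column;
    the realized cut is stored in ``result.attrs['median']``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValidationError("median_split needs n >= 2")
    if np.unique(s).size < 2:
        raise DegenerateDataError("median_split undefined: all scores identical")
    med = float(np.median(s))
    labels = np.where(s <= med, "low", "high")
    if (labels == "high").sum() == 0:
        raise DegenerateDataError("median_split degenerate: no scores above the median")
    out = pd.DataFrame({"score": s, "group": labels})
    out.attrs["median"] = med
    out.attrs["n_low"] = int((labels == "low").sum())
    out.attrs["n_high"] = int((labels == "high").sum())
    return out


def two_sample_t(a, b, welch: bool = False):
    """Two-sample t-test, pooled-variance Student's by default.

    Returns ``(t, df, p)`` with a two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_sample_t needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateDataError("two_sample_t undefined: zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def holm_bonferroni(pvals, alpha: float = 0.05, family: str = "") -> AdjustedTests:
    """Holm step-down multiple-testing correction.

    Sorted ascending, the j-th adjusted p-value is
    max_{i <= j} min(1, (m - i + 1) p_(i)); hypotheses are rejected while
    the adjusted value stays <= alpha, which controls family-wise error at
    alpha for any dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("holm_bonferroni needs a nonempty 1-d p-value vector")
    if not ((p >= 0) & (p <= 1)).all() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return AdjustedTests(
        pvalues_raw=p, pvalues_adjusted=adjusted, reject=reject, alpha=alpha, family=family
    )
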