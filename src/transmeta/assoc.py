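"""Per-stratum SNP association under an additive genetic model.

One biallelic SNP enters as a single dosage term (count of the effect
allele, 0/1/2); quantitative traits are fit by OLS (t-reference Wald
p-values, residual-variance SEs), binary traits by maximum-likelihood
logistic regression (Newton/IRLS, normal Wald p-values).  Covariate
adjustment is configurable; categorical covariates (study site,
education level) are expanded to indicator columns against a first-level
reference.  Analysis is complete-case per model: rows missing any model
variable are dropped and the rows actually used are reported as ``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    MonomorphicSNPError,
    SeparationError,
    SingularDesignError,
    ZeroVarianceError,
)


@dataclass(frozen=True)
class ModelSpec:
    """Trait, trait kind, covariates and optional transform for one model."""

    trait: str
    kind: str = "quantitative"  # "quantitative" | "binary"
    covariates: Tuple[str, ...] = ()
    transform: str = "identity"  # "identity" | "sqrt"
    dosage_col: str = "dosage"

    def __post_init__(self):
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.transform not in ("identity", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform != "identity" and self.kind != "quantitative":
            raise ValueError("transforms apply to quantitative traits only")


@dataclass(frozen=True)
class AssocEstimate:
    """Per-stratum per-trait association summary (per effect-allele copy)."""

    stratum: str
    trait: str
    beta: float
    se: float
    p: float
    n: int
    kind: str


@dataclass(frozen=True)
class FitResult:
    """Coefficient estimates with SEs and two-sided Wald p-values."""

    names: Tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    df_resid: float
    loglik: float
    method: str

    def coef(self, name: str) -> Tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.params[i]), float(self.se[i]), float(self.p[i])


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise :class:`SingularDesignError` naming the collinear columns.

    Uses column-pivoted QR: columns pivoted beyond the numerical rank are
    the ones expressible as combinations of the others.
    """
    X = np.asarray(X, dtype=float)
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in piv[rank:])
        raise SingularDesignError(bad)


def fit_linear(y, X, names: Optional[Sequence[str]] = None) -> FitResult:
    """Ordinary least squares with t-reference two-sided Wald p-values.

    SEs use the unbiased residual-variance estimator (df = n - k).
    """
    X = pd.DataFrame(X)
    if names is not None:
        X.columns = list(names)
    names = tuple(str(c) for c in X.columns)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"n={n} rows cannot identify {k} parameters")
    check_full_rank(X.to_numpy(), names)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    return FitResult(
        names=names, params=np.asarray(res.params), se=np.asarray(res.bse),
        p=np.asarray(res.pvalues), n=n, df_resid=float(res.df_resid),
        loglik=float(res.llf), method="ols",
    )


_SEP_COEF_BOUND = 30.0  # |log-odds| beyond this signals (quasi-)separation


def fit_logistic(y, X, names: Optional[Sequence[str]] = None, maxiter: int = 100) -> FitResult:
    """Maximum-likelihood logistic regression (Newton), normal Wald p-values.

    Raises :class:`SeparationError` on perfect or quasi-perfect
    separation (detected by statsmodels or by diverging coefficients)
    and :class:`ConvergenceError` if Newton exhausts its iterations.
    """
    X = pd.DataFrame(X)
    if names is not None:
        X.columns = list(names)
    names = tuple(str(c) for c in X.columns)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binary response must be coded 0/1")
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"n={n} rows cannot identify {k} parameters")
    check_full_rank(X.to_numpy(), names)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    model = sm.Logit(y, X.to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix in logistic fit: {exc}") from exc
    params = np.asarray(res.params)
    if np.any(np.abs(params) > _SEP_COEF_BOUND) or not np.all(np.isfinite(params)):
        raise SeparationError(
            f"diverging coefficients (max |beta|={np.abs(params).max():.1f}); "
            "data are (quasi-)separated"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge in {maxiter} iterations")
    return FitResult(
        names=names, params=params, se=np.asarray(res.bse),
        p=np.asarray(res.pvalues), n=n, df_resid=float(res.df_resid),
        loglik=float(res.llf), method="logit-newton",
    )


def build_design(
    df: pd.DataFrame, covariates: Sequence[str], add_const: bool = True
) -> pd.DataFrame:
    """Numeric design block for ``covariates``, categoricals expanded.

    Object/categorical columns become 0/1 indicators against a
    first-level (sorted) reference.
    """
    parts = []
    if add_const:
        parts.append(pd.Series(1.0, index=df.index, name="const"))
    for name in covariates:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _subset(cohort: pd.DataFrame, stratum: Optional[str]) -> pd.DataFrame:
    if stratum is None:
        return cohort
    sub = cohort[cohort["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} not present in cohort")
    return sub


def snp_assoc(cohort: pd.DataFrame, stratum: Optional[str], model: ModelSpec) -> AssocEstimate:
    """Additive SNP association for one trait in one stratum.

    ``stratum=None`` pools all subjects and adds stratum indicator
    covariates.  The square-root transform (for right-skewed fatty-acid
    ratios) is applied before fitting.
    """
    needed = [model.trait, model.dosage_col, *model.covariates]
    sub = _subset(cohort, stratum)
    covs = list(model.covariates)
    if stratum is None and cohort["stratum"].nunique() > 1:
        covs.append("stratum")
        needed.append("stratum")
    sub = sub.dropna(subset=[c for c in dict.fromkeys(needed)])
    if sub.empty:
        raise InsufficientDataError("no complete cases for this model")
    dosage = sub[model.dosage_col].astype(float)
    if dosage.nunique() < 2:
        raise MonomorphicSNPError(
            f"dosage is monomorphic in the analysis subset (stratum={stratum!r})"
        )
    y = sub[model.trait].astype(float)
    if model.kind == "quantitative" and y.nunique() < 2:
        raise ZeroVarianceError(f"trait {model.trait!r} is constant in the subset")
    if model.transform == "sqrt":
        if (y < 0).any():
            raise ValueError("square-root transform requires non-negative trait values")
        y = np.sqrt(y)

    X = build_design(sub, covs)
    X.insert(1, model.dosage_col, dosage)
    fit = fit_linear(y, X) if model.kind == "quantitative" else fit_logistic(y, X)
    beta, se, p = fit.coef(model.dosage_col)
    return AssocEstimate(
        stratum=stratum if stratum is not None else "pooled",
        trait=model.trait, beta=beta, se=se, p=p, n=fit.n, kind=model.kind,
    )


def assoc_by_stratum(cohort: pd.DataFrame, model: ModelSpec) -> list:
    """:func:`snp_assoc` for every stratum, in order of first appearance."""
    strata = list(dict.fromkeys(cohort["stratum"]))
    return [snp_assoc(cohort, s, model) for s in strata]
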