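"""Difference-in-coefficients mediation with bias-corrected bootstrap CIs.

The mediation effect of M in the SNP→outcome association is estimated as
the change in the SNP coefficient when the mediator is added:

    Model 1:  Y ~ G + X          (SNP coefficient c1)
    Model 2:  Y ~ G + M + X      (SNP coefficient c2)
    diff   =  c2 - c1

In a linear structural model ``M = a G + ..., Y = c G + b M + ...`` the
difference converges to ``-(a*b)``, minus the indirect effect.  Both
models are fit on the identical complete-case subset.

Uncertainty comes from a nonparametric pairs bootstrap (whole subject
rows resampled with replacement within stratum), with bias-corrected
(BC, no acceleration) percentile intervals:

    z0 = Phi^-1( (#{theta* < theta_hat} + 0.5 #{theta* = theta_hat}) / B )
    alpha_1 = Phi(2 z0 + z_{alpha/2}),  alpha_2 = Phi(2 z0 + z_{1-alpha/2})

and the CI endpoints are the empirical ``alpha_1``/``alpha_2`` quantiles
of the bootstrap distribution.  The two-sided p-value is the smallest
alpha at which the BC interval excludes 0, found by bisection to a
tolerance of 1/B.  Resamples in which either model is singular (e.g. a
monomorphic resampled dosage) are redrawn, capped at 10% of B.

Across strata, the per-stratum differences are combined by
inverse-variance fixed-effects meta-analysis using the bootstrap SD as
each stratum's standard error.

The bootstrap is vectorised: resamples are represented as multinomial
row weights and all B weighted normal-equation solves are batched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import build_design, check_full_rank
from .exceptions import (
    DegenerateBootstrapError,
    InsufficientDataError,
    MonomorphicSNPError,
)
from .meta import MetaResult, StudyEstimate, fixed_effects_meta


@dataclass(frozen=True)
class MediationSpec:
    """Outcome, mediator, covariates and bootstrap settings for one analysis."""

    outcome: str
    mediator: str
    covariates: Tuple[str, ...] = ()
    transform: str = "identity"  # mediator transform: "identity" | "sqrt"
    dosage_col: str = "dosage"
    B: int = 1000
    seed: Optional[int] = None
    level: float = 0.95

    def __post_init__(self):
        if self.B < 200:
            raise ValueError("bootstrap needs B >= 200 replicates")
        if not 0.0 < self.level < 1.0:
            raise ValueError("CI level must be in (0, 1)")
        if self.transform not in ("identity", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class MediationResult:
    stratum: str
    coef_model1: float
    coef_model2: float
    diff: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    z0: float
    boot_se: float
    level: float
    B: int
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# point estimate

_DOSAGE_IDX = 1  # design layout: [const, dosage, covariates..., (mediator)]


def _prepare(cohort: pd.DataFrame, stratum: Optional[str], spec: MediationSpec):
    """Complete-case arrays: response, Model-1 design, mediator column."""
    cols = [spec.outcome, spec.mediator, spec.dosage_col, *spec.covariates]
    sub = cohort if stratum is None else cohort[cohort["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} not present in cohort")
    sub = sub.dropna(subset=list(dict.fromkeys(cols)))
    if sub.empty:
        raise InsufficientDataError("no complete cases on the union of model variables")
    if sub[spec.dosage_col].nunique() < 2:
        raise MonomorphicSNPError(f"dosage is monomorphic in stratum {stratum!r}")
    y = sub[spec.outcome].to_numpy(dtype=float)
    m = sub[spec.mediator].to_numpy(dtype=float)
    if spec.transform == "sqrt":
        if (m < 0).any():
            raise ValueError("square-root transform requires a non-negative mediator")
        m = np.sqrt(m)
    X1 = build_design(sub, list(spec.covariates))
    X1.insert(_DOSAGE_IDX, spec.dosage_col, sub[spec.dosage_col].astype(float))
    names = tuple(X1.columns) + (spec.mediator,)
    X2 = np.column_stack([X1.to_numpy(dtype=float), m])
    check_full_rank(X2, names)  # raises naming the collinear columns
    return y, X2, names


def _solve_pair(y: np.ndarray, X2: np.ndarray) -> Tuple[float, float]:
    """SNP coefficients of Model 1 (without last column) and Model 2."""
    c2 = np.linalg.lstsq(X2, y, rcond=None)[0][_DOSAGE_IDX]
    c1 = np.linalg.lstsq(X2[:, :-1], y, rcond=None)[0][_DOSAGE_IDX]
    return float(c1), float(c2)


def diff_coefficients(
    cohort: pd.DataFrame, stratum: Optional[str], spec: MediationSpec
) -> Tuple[float, float, float, int]:
    """(coef_model1, coef_model2, difference, n used) for one stratum."""
    y, X2, _ = _prepare(cohort, stratum, spec)
    c1, c2 = _solve_pair(y, X2)
    return c1, c2, c2 - c1, len(y)


# ---------------------------------------------------------------------------
# bias-corrected bootstrap

def bc_z0(samples: np.ndarray, point: float) -> float:
    """Bias-correction constant with the half-count convention for ties."""
    b = len(samples)
    prop = (np.sum(samples < point) + 0.5 * np.sum(samples == point)) / b
    prop = min(max(prop, 0.5 / b), 1.0 - 0.5 / b)
    return float(stats.norm.ppf(prop))


def bc_interval(samples: np.ndarray, point: float, level: float) -> Tuple[float, float, float]:
    """(lower, upper, z0) of the bias-corrected percentile interval."""
    z0 = bc_z0(samples, point)
    alpha = 1.0 - level
    a1 = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(alpha / 2.0))
    a2 = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(1.0 - alpha / 2.0))
    lo, hi = np.quantile(samples, [a1, a2])
    return float(lo), float(hi), z0


def bc_pvalue(samples: np.ndarray, point: float, tol: Optional[float] = None) -> float:
    """Smallest two-sided alpha at which the BC interval excludes 0.

    Found by bisection over alpha; tolerance defaults to 1/B, which is
    also the floor: p-values below the bootstrap resolution are reported
    at 1/B.
    """
    b = len(samples)
    tol = tol if tol is not None else 1.0 / b

    def excludes(alpha: float) -> bool:
        lo, hi, _ = bc_interval(samples, point, 1.0 - alpha)
        return lo > 0.0 or hi < 0.0

    hi_a = 1.0 - 1e-9
    if not excludes(hi_a):
        return 1.0
    lo_a = 0.0
    if excludes(tol):
        return tol
    while hi_a - lo_a > tol:
        mid = 0.5 * (lo_a + hi_a)
        if excludes(mid):
            hi_a = mid
        else:
            lo_a = mid
    return float(hi_a)


def _weighted_diffs(y: np.ndarray, X2: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bootstrap differences for multinomial row-weight matrix W (B, n).

    Solves the weighted normal equations of Models 1 and 2 for every
    resample in one batch; singular or ill-conditioned resamples come
    back NaN for the caller to redraw.
    """
    n, p2 = X2.shape
    iu, ju = np.triu_indices(p2)
    Z = X2[:, iu] * X2[:, ju]  # (n, p2*(p2+1)/2) pairwise products
    Gu = W @ Z  # (B, q) weighted upper-triangular grams
    G = np.empty((W.shape[0], p2, p2))
    G[:, iu, ju] = Gu
    G[:, ju, iu] = Gu
    R = W @ (X2 * y[:, None])  # (B, p2)

    out = np.full(W.shape[0], np.nan)
    # condition screen on the Model-2 gram; the Model-1 gram is its leading
    # principal submatrix, so a well-conditioned G implies a usable G1
    with np.errstate(all="ignore"):
        eig = np.linalg.eigvalsh(G)
    good = np.isfinite(eig).all(axis=1) & (eig[:, 0] > 1e-10 * np.abs(eig[:, -1]))
    if good.any():
        Gg, Rg = G[good], R[good]
        c2 = np.linalg.solve(Gg, Rg[..., None])[:, _DOSAGE_IDX, 0]
        c1 = np.linalg.solve(Gg[:, :-1, :-1], Rg[:, :-1, None])[:, _DOSAGE_IDX, 0]
        out[good] = c2 - c1
    return out


def bc_bootstrap_ci(
    cohort: pd.DataFrame, stratum: Optional[str], spec: MediationSpec
) -> MediationResult:
    """Full BC-bootstrap mediation analysis for one stratum."""
    if spec.seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    y, X2, _ = _prepare(cohort, stratum, spec)
    n = len(y)
    c1, c2 = _solve_pair(y, X2)
    point = c2 - c1

    rng = np.random.default_rng(spec.seed)
    max_redraws = int(0.10 * spec.B)
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=spec.B).astype(float)
    theta = _weighted_diffs(y, X2, W)
    n_redrawn = 0
    while np.isnan(theta).any():
        bad = np.flatnonzero(np.isnan(theta))
        n_redrawn += len(bad)
        if n_redrawn > max_redraws:
            raise DegenerateBootstrapError(
                f"{n_redrawn} singular bootstrap resamples exceed the 10% cap "
                f"({max_redraws} of B={spec.B})"
            )
        Wb = rng.multinomial(n, np.full(n, 1.0 / n), size=len(bad)).astype(float)
        theta[bad] = _weighted_diffs(y, X2, Wb)

    lo, hi, z0 = bc_interval(theta, point, spec.level)
    p = bc_pvalue(theta, point)
    return MediationResult(
        stratum=stratum if stratum is not None else "pooled",
        coef_model1=c1, coef_model2=c2, diff=point,
        ci_low=lo, ci_high=hi, p=p, n=n, z0=z0,
        boot_se=float(np.std(theta, ddof=1)), level=spec.level, B=spec.B,
        n_redrawn=n_redrawn,
    )


def mediation_by_stratum(
    cohort: pd.DataFrame, spec: MediationSpec
) -> list:
    """BC-bootstrap mediation for every stratum, with per-stratum sub-seeds."""
    strata = list(dict.fromkeys(cohort["stratum"]))
    out = []
    for i, s in enumerate(strata):
        sub_spec = MediationSpec(
            outcome=spec.outcome, mediator=spec.mediator,
            covariates=spec.covariates, transform=spec.transform,
            dosage_col=spec.dosage_col, B=spec.B,
            seed=(spec.seed + i if spec.seed is not None else None),
            level=spec.level,
        )
        out.append(bc_bootstrap_ci(cohort, s, sub_spec))
    return out


def mediation_meta(results: Sequence[MediationResult]) -> MetaResult:
    """Fixed-effects combination of per-stratum differences.

    Uses each stratum's bootstrap SD as its standard error — the only
    self-consistent uncertainty available to the combiner.
    """
    if len(results) < 2:
        raise ValueError("mediation meta-analysis needs at least two strata")
    ests = [
        StudyEstimate(label=r.stratum, beta=r.diff, se=r.boot_se, n=r.n)
        for r in results
    ]
    return fixed_effects_meta(ests)
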