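"""Trial-style survival analyses: Cox PH fits and gene x treatment tests.

The Cox proportional-hazards model is fit by Newton maximization of the
partial likelihood, with Breslow tie handling by default (Efron behind a
flag; the two coincide on tie-free data).  Standard errors come from the
inverse observed information; Wald p-values are two-sided normal.
Convergence requires the maximum absolute score below ``tol`` (1e-8).

Degenerate inputs raise explicit errors: no events, a constant or
collinear covariate, a covariate that perfectly separates events in time
(monotone likelihood — detected by diverging coefficients).

The gene x treatment interaction test fits SNP dosage, randomized arm,
their product and any adjustment covariates in one model and reports the
Wald test of the product term.  Pooled analyses across population strata
include stratum indicator covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from scipy import stats

from .assoc import AssocEstimate, ModelSpec, assoc_by_stratum, build_design, check_full_rank
from .exceptions import (
    ConvergenceError,
    NoEventsError,
    SeparationError,
    SingularDesignError,
)
from .meta import MetaResult, StudyEstimate, dersimonian_laird_meta


@dataclass(frozen=True)
class SurvivalFit:
    """Per-term log hazard ratios with SEs and two-sided Wald p-values."""

    names: Tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    loglik: float
    converged: bool
    ties: str

    def coef(self, name: str) -> Tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.params[i]), float(self.se[i]), float(self.p[i])


def _risk_sums(t_sorted, w, Xw, Zw, first):
    """Reverse-cumulative risk-set sums evaluated at each row's tie group."""
    rs0 = np.cumsum(w[::-1])[::-1]
    rs1 = np.cumsum(Xw[::-1], axis=0)[::-1]
    rs2 = np.cumsum(Zw[::-1], axis=0)[::-1]
    return rs0[first], rs1[first], rs2[first]


def _partial_quantities(beta, t, e, X, ties, first, iu, ju):
    """(loglik, score, information) of the partial likelihood at ``beta``."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # overflow guard; partial likelihood is invariant
    w = np.exp(eta)
    Xw = X * w[:, None]
    Zw = X[:, iu] * X[:, ju] * w[:, None]
    S0, S1, S2u = _risk_sums(t, w, Xw, Zw, first)

    ev = e.astype(bool)
    q = len(iu)
    if ties == "breslow":
        loglik = float(np.sum(eta[ev]) - np.sum(np.log(S0[ev])))
        mu = S1[ev] / S0[ev][:, None]
        score = X[ev].sum(axis=0) - mu.sum(axis=0)
        info_u = (S2u[ev] / S0[ev][:, None]).sum(axis=0)
        info = np.zeros((p, p))
        info[iu, ju] = info_u
        info[ju, iu] = info_u
        info -= mu.T @ mu
        return loglik, score, info

    # Efron: loop over tied event-time groups
    loglik = float(np.sum(eta[ev]))
    score = X[ev].sum(axis=0).astype(float)
    info = np.zeros((p, p))
    ev_idx = np.flatnonzero(ev)
    groups = {}
    for i in ev_idx:
        groups.setdefault(first[i], []).append(i)
    for f, members in groups.items():
        d = len(members)
        s0, s1 = S0[f], S1[f]
        s2 = np.zeros((p, p))
        s2[iu, ju] = S2u[f]
        s2[ju, iu] = S2u[f]
        t0 = w[members].sum()
        t1 = Xw[members].sum(axis=0)
        t2u = Zw[members].sum(axis=0)
        t2 = np.zeros((p, p))
        t2[iu, ju] = t2u
        t2[ju, iu] = t2u
        for l in range(d):
            frac = l / d
            d0 = s0 - frac * t0
            d1 = s1 - frac * t1
            d2 = s2 - frac * t2
            loglik -= np.log(d0)
            score -= d1 / d0
            info += d2 / d0 - np.outer(d1 / d0, d1 / d0)
    return loglik, score, info


def _prepare_cox(time, event, X, names):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    names = tuple(names)
    if np.any(t < 0):
        raise ValueError("follow-up times must be non-negative")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("event indicator must be coded 0/1")
    if int(e.sum()) < 1:
        raise NoEventsError("survival data contain no events")
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise SingularDesignError(const, f"constant covariate column(s): {const}")
    check_full_rank(X - X.mean(axis=0), names)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order].astype(int), X[order]
    first = np.searchsorted(t, t, side="left")
    return t, e, X - X.mean(axis=0), names, X.mean(axis=0)


def cox_partial_loglik(beta, time, event, X, ties: str = "breslow") -> float:
    """Partial log-likelihood at ``beta`` (for diagnostics and oracles)."""
    t, e, Xc, names, _ = _prepare_cox(time, event, X, None)
    iu, ju = np.triu_indices(Xc.shape[1])
    ll, _, _ = _partial_quantities(np.asarray(beta, dtype=float), t, e, Xc, ties,
                                   np.searchsorted(t, t, side="left"), iu, ju)
    return ll


_COX_COEF_BOUND = 50.0


def fit_cox(
    time, event, X, names: Optional[Sequence[str]] = None,
    ties: str = "breslow", max_iter: int = 50, tol: float = 1e-8,
) -> SurvivalFit:
    """Cox proportional-hazards fit by Newton iteration.

    Parameters are log hazard ratios.  ``ties`` is ``"breslow"``
    (default) or ``"efron"``.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    t, e, Xc, names, _ = _prepare_cox(time, event, X, names)
    n, p = Xc.shape
    first = np.searchsorted(t, t, side="left")
    iu, ju = np.triu_indices(p)

    beta = np.zeros(p)
    ll, score, info = _partial_quantities(beta, t, e, Xc, ties, first, iu, ju)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halve until the partial likelihood increases (tolerance is
        # relative: near the optimum the log-likelihood moves at float noise)
        factor, accepted = 1.0, False
        ll_slack = 1e-9 * max(1.0, abs(ll))
        for _h in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _partial_quantities(
                cand, t, e, Xc, ties, first, iu, ju
            )
            score_ok = np.all(np.isfinite(score_new)) and np.max(np.abs(score_new)) < tol
            if np.isfinite(ll_new) and (ll_new >= ll - ll_slack or score_ok):
                beta, ll, score, info = cand, ll_new, score_new, info_new
                accepted = True
                break
            factor *= 0.5
        if not accepted:
            raise SeparationError(
                "step halving failed to increase the partial likelihood; "
                "a covariate may perfectly order the events (monotone likelihood)"
            )
        if np.max(np.abs(beta)) > _COX_COEF_BOUND:
            raise SeparationError(
                f"diverging coefficients (max |beta|={np.abs(beta).max():.1f}); "
                "monotone partial likelihood"
            )
    else:
        if np.max(np.abs(score)) < tol:
            converged = True
    if not converged:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return SurvivalFit(
        names=names, params=beta, se=se, p=pvals, n=n,
        n_events=int(e.sum()), loglik=ll, converged=converged, ties=ties,
    )


def interaction_test(
    cohort: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    dosage_col: str = "dosage",
    treatment_col: str = "treatment",
    covariates: Sequence[str] = (),
    include_stratum: bool = True,
    include_interaction: bool = True,
    ties: str = "breslow",
) -> SurvivalFit:
    """Cox model with SNP, treatment and (optionally) their product term.

    The interaction term's Wald test asks whether randomized treatment
    modifies the per-allele log hazard ratio.  Pooled analyses include
    stratum indicators when several strata are present.
    """
    cols = [time_col, event_col, dosage_col, treatment_col, *covariates]
    if include_stratum and cohort["stratum"].nunique() > 1:
        cols.append("stratum")
    sub = cohort.dropna(subset=list(dict.fromkeys(cols)))
    trt = sub[treatment_col]
    if not np.all(np.isin(trt, (0, 1))):
        raise ValueError("treatment arm must be coded 0/1")

    parts = {
        dosage_col: sub[dosage_col].astype(float),
        treatment_col: trt.astype(float),
    }
    if include_interaction:
        parts[f"{dosage_col}:{treatment_col}"] = parts[dosage_col] * parts[treatment_col]
    X = pd.DataFrame(parts, index=sub.index)
    extra = list(covariates)
    if include_stratum and cohort["stratum"].nunique() > 1:
        extra.append("stratum")
    if extra:
        X = pd.concat([X, build_design(sub, extra, add_const=False)], axis=1)
    return fit_cox(
        sub[time_col], sub[event_col], X.to_numpy(dtype=float),
        names=tuple(X.columns), ties=ties,
    )


def baseline_biomarker_assoc(
    cohort: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = (),
    transform: str = "identity",
) -> Tuple[list, MetaResult]:
    """Per-stratum SNP association with a baseline biomarker, plus
    DerSimonian-Laird random-effects combination across strata."""
    model = ModelSpec(trait=trait, kind="quantitative",
                      covariates=tuple(covariates), transform=transform)
    ests = assoc_by_stratum(cohort, model)
    studies = [StudyEstimate(label=a.stratum, beta=a.beta, se=a.se, n=a.n) for a in ests]
    return ests, dersimonian_laird_meta(studies)
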