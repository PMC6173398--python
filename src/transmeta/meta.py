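"""Meta-analysis of per-stratum association estimates.

Implements the three combiners the pipeline needs:

* inverse-variance **fixed-effects** meta-analysis (one common effect;
  weights :math:`w_i = 1/\\mathrm{se}_i^2`),
* **Cochran's Q** heterogeneity with :math:`I^2` (percent of total
  variance attributed to between-stratum heterogeneity, floored at 0),
* **DerSimonian-Laird random effects** (moment estimator of the
  between-stratum variance :math:`\\tau^2`, truncated at 0).

p-values are two-sided normal throughout, matching the convention of
the METAL summary-statistics tooling these results round-trip with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StudyEstimate:
    """One stratum's (effect, standard error) with an optional sample size."""

    label: str
    beta: float
    se: float
    n: Optional[int] = None

    def __post_init__(self):
        if not math.isfinite(self.beta):
            raise ValueError(f"non-finite effect for {self.label!r}: {self.beta}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be positive for {self.label!r}")


@dataclass(frozen=True)
class MetaResult:
    """Combined effect plus heterogeneity diagnostics.

    ``i2`` is in percent and floored at 0; ``tau2`` is 0 for the fixed
    method by construction.  ``q``, ``het_p`` and ``i2`` are NaN when
    only one stratum was combined (heterogeneity is then undefined).
    """

    method: str  # "fixed" | "dl-random"
    beta: float
    se: float
    z: float
    p: float
    q: float
    df: int
    het_p: float
    i2: float
    tau2: float
    k: int


def _validate(estimates: Sequence[StudyEstimate], k_min: int = 1):
    if len(estimates) < k_min:
        raise ValueError(f"need at least {k_min} estimates, got {len(estimates)}")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)):
        raise ValueError("all standard errors must be positive and finite")
    if not np.all(np.isfinite(betas)):
        raise ValueError("all effects must be finite")
    return betas, ses


def fixed_effects_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects combination.

    beta = sum(w_i b_i)/sum(w_i), se = (sum w_i)^{-1/2}, w_i = 1/se_i^2;
    two-sided normal p.  Heterogeneity fields are filled from Cochran's Q
    when k >= 2, else NaN.
    """
    betas, ses = _validate(estimates, k_min=1)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    k = len(estimates)
    if k >= 2:
        q, df, het_p, i2 = cochran_heterogeneity(estimates)
    else:
        q, df, het_p, i2 = math.nan, 0, math.nan, math.nan
    return MetaResult(
        method="fixed", beta=beta, se=se, z=z, p=p,
        q=q, df=df, het_p=het_p, i2=i2, tau2=0.0, k=k,
    )


def cochran_heterogeneity(estimates: Sequence[StudyEstimate]):
    """Cochran's Q, its df, the upper-tail chi-square p, and I2 (percent).

    Q = sum w_i (b_i - b_FE)^2 with fixed-effects weights;
    I2 = max(0, (Q - df)/Q) * 100 (0 when Q = 0).
    """
    betas, ses = _validate(estimates, k_min=2)
    w = 1.0 / ses**2
    beta_fe = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = len(estimates) - 1
    het_p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q == 0.0 else max(0.0, (q - df) / q) * 100.0
    return q, df, het_p, i2


def dersimonian_laird_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects combination.

    tau2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w); the
    combined effect uses weights 1/(se_i^2 + tau2).  When Q <= df the
    truncation gives tau2 = 0 and the result equals the fixed-effects
    combination exactly.
    """
    betas, ses = _validate(estimates, k_min=2)
    w = 1.0 / ses**2
    q, df, het_p, i2 = cochran_heterogeneity(estimates)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        method="dl-random", beta=beta, se=se, z=z, p=p,
        q=q, df=df, het_p=het_p, i2=i2, tau2=tau2, k=len(estimates),
    )
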